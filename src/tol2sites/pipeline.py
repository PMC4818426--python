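"""End-to-end pipeline: simulate -> map -> TSD -> bias test -> hotspots -> motif.

Each randomized stage derives its seed deterministically from the run
seed plus a stage tag, so a stage re-run in isolation reproduces its
output and two identical configs produce byte-identical summaries.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import junctions, plasmid as plasmid_io, stats, synthetic
from .errors import Tol2SitesError
from .events import read_events, write_events
from .tsd import TsdCall, tsd_rate

DEFAULT_FEATURE_SPEC = [
    ["sv40_polyA", 0.10, 0.64],
    ["ampR", 0.25, 0.50],
    ["ori", 0.15, 0.50],
    ["backbone", 0.50, 0.50],
]


def stage_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed ^ zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (YAML-serializable)."""

    seed: int = 42
    plasmid_length: int = 4000
    feature_spec: list = field(default_factory=lambda: [list(r) for r in DEFAULT_FEATURE_SPEC])
    n_events: int = 500
    n_experiments: int = 4
    beta_at: float = 8.0
    at_window: int = 51
    tsd_fidelity: float = 0.86
    flank_len: int = 24
    min_terminal_match: int = 14
    min_anchor: int = 16
    max_tsd: int = 12
    n_sims: int = 10_000
    hotspot_tolerance: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def bias(self) -> synthetic.BiasModel:
        return synthetic.BiasModel(
            beta_at=self.beta_at, window=self.at_window, tsd_fidelity=self.tsd_fidelity
        )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full synthetic-demo pipeline into ``outdir``.

    Stages: simulate reference + events + junction reads; map junctions
    back to events; TSD summary; feature occupancy and Monte Carlo bias
    test; hotspots; motif; AT enrichment.  Writes standard-format files
    per stage plus a machine-readable ``summary.json`` and the
    effective config, and returns the summary dict.  A stage failure
    raises with the stage name attached.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        target = synthetic.make_target_plasmid(
            config.plasmid_length,
            [tuple(r) for r in config.feature_spec],
            seed=stage_seed(config.seed, "plasmid"),
        )
        plasmid_io.write_fasta(target, out / "target.fa")
        plasmid_io.write_gff3(target, out / "target.gff3")
        plasmid_io.write_bed(target, out / "target.bed")
        n_per = config.n_events // config.n_experiments
        truth = synthetic.simulate_experiments(
            target, n_per, config.n_experiments, config.bias(), stage_seed(config.seed, "events")
        )
        write_events(truth, out / "events_truth.tsv")
        reads = synthetic.emit_junction_reads(
            truth, target, synthetic.TransposonEnds(), config.flank_len
        )
        junctions.write_junctions_fasta(reads, out / "junctions.fasta")
        summary["n_events_simulated"] = len(truth)
        summary["n_records_in"] = len(reads)

        stage = "map-junctions"
        records = junctions.read_junctions_fasta(out / "junctions.fasta")
        events, rejects, accounting = junctions.process_junctions(
            records,
            target,
            synthetic.TransposonEnds(),
            min_terminal_match=config.min_terminal_match,
            min_anchor=config.min_anchor,
            max_tsd=config.max_tsd,
        )
        write_events(events, out / "events_called.tsv")
        with open(out / "rejects.tsv", "w") as fh:
            fh.write("record_id\treason\n")
            for rid, reason in rejects:
                fh.write(f"{rid}\t{reason}\n")
        summary["n_events_called"] = len(events)
        summary["record_accounting"] = dict(sorted(accounting.items()))

        stage = "tsd"
        calls = [TsdCall(e.tsd_seq, e.tsd_len, e.canonical) for e in events]
        frac, hist = tsd_rate(calls)
        summary["canonical_tsd_fraction"] = round(frac, 6)
        summary["tsd_length_histogram"] = {str(k): v for k, v in hist.items()}

        stage = "bias-test"
        occupancy = stats.feature_occupancy(events, target)
        occupancy.to_frame().to_csv(out / "occupancy.tsv", sep="\t", index=False)
        mc = stats.monte_carlo_bias_test(
            occupancy, n_sims=config.n_sims, seed=stage_seed(config.seed, "bias-test")
        )
        mc.to_frame().to_csv(out / "bias_test.tsv", sep="\t", index=False)
        summary["p_greater"] = {n: round(float(p), 6) for n, p in zip(mc.names, mc.p_greater)}
        summary["p_less"] = {n: round(float(p), 6) for n, p in zip(mc.names, mc.p_less)}

        stage = "hotspots"
        hotspots = stats.call_hotspots(events, tolerance=config.hotspot_tolerance)
        stats.write_hotspots_bed(hotspots, target.name, out / "hotspots.bed")
        summary["n_hotspots"] = len(hotspots)

        stage = "motif"
        motif = stats.build_motif(events, target)
        motif.to_frame().to_csv(out / "motif_counts.tsv", sep="\t")
        (out / "consensus.txt").write_text(motif.consensus + "\n")
        summary["consensus"] = motif.consensus
        summary["motif_n_sites"] = motif.n_sites

        stage = "at-enrichment"
        site_at, background_at, per_feature = stats.at_enrichment(
            events, target, window=config.at_window
        )
        summary["site_at_fraction"] = round(site_at, 4)
        summary["background_at_fraction"] = round(background_at, 4)
        summary["feature_at_fractions"] = {k: round(v, 4) for k, v in per_feature.items()}
    except Exception as exc:  # re-raise with stage context, counts preserved
        raise Tol2SitesError(
            f"pipeline failed at stage {stage!r} "
            f"(events so far: {summary.get('n_events_called', 0)}): {exc}"
        ) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    render_report(out)
    return summary


def render_report(outdir: str | Path) -> str:
    """Human-readable markdown report over a run directory; missing
    stage outputs are marked "not computed" with a partial-report
    warning line.  Regeneration is idempotent."""
    out = Path(outdir)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise Tol2SitesError("summary.json missing: run the pipeline first")
    s = json.loads(summary_path.read_text())
    missing: list[str] = []
    lines = ["# Insertion-site analysis report", ""]

    lines += ["## Input and record accounting", ""]
    acc = s.get("record_accounting")
    if acc is None:
        missing.append("record accounting")
        lines += ["not computed", ""]
    else:
        lines.append(f"- junction records in: {s.get('n_records_in')}")
        for reason, n in acc.items():
            lines.append(f"- {reason}: {n}")
        lines.append(f"- events called: {s.get('n_events_called')}")
        lines.append("")

    lines += ["## Target-site duplications", ""]
    if "canonical_tsd_fraction" not in s:
        missing.append("tsd")
        lines += ["not computed", ""]
    else:
        lines.append(f"- canonical 8-bp fraction: {s['canonical_tsd_fraction']:.3f}")
        hist = ", ".join(f"{k}:{v}" for k, v in s.get("tsd_length_histogram", {}).items())
        lines += [f"- length histogram: {hist}", ""]

    lines += ["## Feature occupancy vs length-proportional expectation", ""]
    occ = out / "bias_test.tsv"
    if not occ.exists():
        missing.append("bias test")
        lines += ["not computed", ""]
    else:
        lines += [occ.read_text().rstrip(), ""]

    lines += ["## Hotspots", ""]
    if "n_hotspots" not in s:
        missing.append("hotspots")
        lines += ["not computed", ""]
    else:
        lines += [f"- hotspot count: {s['n_hotspots']} (see hotspots.bed)", ""]

    lines += ["## Integration-site consensus", ""]
    if "consensus" not in s:
        missing.append("motif")
        lines += ["not computed", ""]
    else:
        lines += [
            f"- observed consensus (n = {s.get('motif_n_sites')}): `{s['consensus']}`",
            f"- reference consensus:                `{stats.REFERENCE_CONSENSUS}`",
            "",
        ]

    lines += ["## AT context", ""]
    if "site_at_fraction" not in s:
        missing.append("AT enrichment")
        lines += ["not computed", ""]
    else:
        lines.append(f"- mean insertion-site AT fraction: {s['site_at_fraction']}")
        lines.append(f"- plasmid background AT fraction: {s['background_at_fraction']}")
        for name, at in s.get("feature_at_fractions", {}).items():
            lines.append(f"  - {name}: {at}")
        lines.append("")

    if missing:
        lines.insert(2, f"**Warning: partial report** (missing: {', '.join(missing)})")
        lines.insert(3, "")
    text = "\n".join(lines).rstrip() + "\n"
    (out / "report.md").write_text(text)
    return text
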