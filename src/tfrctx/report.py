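"""Survey-level summaries: group counts, separation histogram, product
categories, regional regulator densities, and report writers."""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .context import ContextCall, Group, TargetPrediction, Thresholds
from .model import AnnotationBundle
from .products import CategorySummary


@dataclass(frozen=True)
class Region:
    """A chromosomal region for density reporting, e.g. the conserved 'core'
    of a linear streptomycete chromosome versus its variable 'arms'."""

    name: str
    replicon_id: str
    start: int
    end: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class SummaryReport:
    n_tfr_total: int
    per_replicon: dict[str, int]
    group_counts: dict[str, int]
    group_fractions: dict[str, float]
    mixed_count: int
    separation_histogram: dict[str, int]
    bin_width: int
    threshold_bp: int
    n_predicted: int
    category_counts: dict[str, int] = field(default_factory=dict)
    ec_counts: dict[str, int] = field(default_factory=dict)
    category_frac_within: dict[str, float] = field(default_factory=dict)
    regional_densities: list[dict] = field(default_factory=list)


def _bin_label(i: int, width: int) -> str:
    # first bin is closed [0, w]; later bins are (i*w, (i+1)*w]
    return f"{i * width}-{(i + 1) * width}"


def summarize(
    calls: Sequence[ContextCall],
    predictions: Sequence[TargetPrediction] = (),
    categories: Optional[CategorySummary] = None,
    regions: Sequence[Region] = (),
    bundle: Optional[AnnotationBundle] = None,
    thresholds: Thresholds = Thresholds(),
    bin_width: int = 100,
) -> SummaryReport:
    """Aggregate pipeline outputs into one report.

    The separation histogram uses bins [0,w], (w,2w], ... so the count
    within the prediction threshold equals the sum of the first
    ``threshold/w`` bins at the default width of 100 bp. Regional densities
    need the annotation bundle to place each regulator gene.
    """
    calls = list(calls)
    n = len(calls)
    group_counts = {g.value: 0 for g in Group}
    per_replicon: dict[str, int] = {}
    mixed = 0
    seps = []
    for c in calls:
        group_counts[c.group.value] += 1
        per_replicon[c.replicon_id] = per_replicon.get(c.replicon_id, 0) + 1
        if c.mixed_flag:
            mixed += 1
        if c.group is Group.DIVERGENT:
            seps.append(c.separation.clamped_bp)

    hist: dict[str, int] = {}
    if seps:
        top = max(seps)
        n_bins = 1 if top == 0 else (top - 1) // bin_width + 1
        for i in range(n_bins):
            hist[_bin_label(i, bin_width)] = 0
        for s in seps:
            i = 0 if s <= bin_width else (s - 1) // bin_width
            hist[_bin_label(i, bin_width)] += 1

    densities = []
    if regions:
        if bundle is None:
            raise ValueError("regional densities need the annotation bundle")
        loci = {c.tfr_locus for c in calls}
        for region in regions:
            count = 0
            rep = bundle.replicon(region.replicon_id)
            for g in rep.genes:
                if g.locus_tag in loci and region.start <= g.start <= region.end:
                    count += 1
            per_mb = count / (region.span_bp / 1e6)
            densities.append(
                {
                    "name": region.name,
                    "replicon": region.replicon_id,
                    "span_bp": region.span_bp,
                    "count": count,
                    "per_mb_raw": per_mb,
                    "per_mb_display": int(round(per_mb)),
                }
            )

    report = SummaryReport(
        n_tfr_total=n,
        per_replicon=per_replicon,
        group_counts=group_counts,
        group_fractions={k: (v / n if n else 0.0) for k, v in group_counts.items()},
        mixed_count=mixed,
        separation_histogram=hist,
        bin_width=bin_width,
        threshold_bp=thresholds.target_distance_max,
        n_predicted=sum(1 for p in predictions if p.predicted),
        category_counts=dict(categories.counts) if categories else {},
        ec_counts={str(k): v for k, v in categories.ec_counts.items()} if categories else {},
        category_frac_within=dict(categories.frac_within_threshold) if categories else {},
        regional_densities=densities,
    )
    check_consistency(report)
    return report


def check_consistency(report: SummaryReport) -> None:
    """Reconciliation pass run before any report is written."""
    if sum(report.group_counts.values()) != report.n_tfr_total:
        raise AssertionError("group counts do not sum to the regulator total")
    if sum(report.per_replicon.values()) != report.n_tfr_total:
        raise AssertionError("per-replicon counts do not sum to the regulator total")
    if report.separation_histogram and (
        sum(report.separation_histogram.values())
        != report.group_counts.get("DIVERGENT", 0)
    ):
        raise AssertionError("histogram counts do not sum to the divergent count")
    for f in report.group_fractions.values():
        if not 0.0 <= f <= 1.0:
            raise AssertionError("group fraction outside [0, 1]")
    if report.category_counts and report.ec_counts:
        if sum(report.ec_counts.values()) != report.category_counts.get("ENZYME", 0):
            raise AssertionError("EC subcounts do not sum to the enzyme count")


def validate_report_dict(d: dict) -> None:
    """Check a report JSON object against the packaged schema (required keys
    and primitive types)."""
    with resources.files("tfrctx.data").joinpath("report.schema.json").open() as fh:
        schema = json.load(fh)
    for key in schema["required"]:
        if key not in d:
            raise ValueError(f"report JSON missing required key {key!r}")
    type_map = {"integer": int, "object": dict, "array": list}
    for key, prop in schema["properties"].items():
        if key in d and prop["type"] in type_map:
            if not isinstance(d[key], type_map[prop["type"]]):
                raise ValueError(f"report key {key!r} should be {prop['type']}")


def _flatten(obj, prefix="") -> dict[str, str]:
    flat = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            flat.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            flat.update(_flatten(v, f"{prefix}{i}."))
    else:
        flat[prefix[:-1]] = json.dumps(obj)
    return flat


def write_report(
    report: SummaryReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json", "tsv", "md"),
    plot: bool = False,
) -> list[Path]:
    """Write the report as machine JSON, flat TSV and/or markdown; a
    histogram plot file is produced only when requested."""
    check_consistency(report)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = asdict(report)
    written = []
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(d, indent=1) + "\n")
        written.append(p)
    if "tsv" in formats:
        p = out_dir / "report.tsv"
        lines = ["key\tvalue"]
        lines += [f"{k}\t{v}" for k, v in _flatten(d).items()]
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    if "md" in formats:
        p = out_dir / "report.md"
        p.write_text(_markdown(report))
        written.append(p)
    if plot:
        p = out_dir / "separation_histogram.png"
        _plot_histogram(report, p)
        written.append(p)
    return written


def read_report_tsv(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines()[1:]:
        k, _, v = line.partition("\t")
        out[k] = v
    return out


def _markdown(report: SummaryReport) -> str:
    lines = [
        "# Regulator genome-context summary",
        "",
        f"Total regulators: {report.n_tfr_total}",
        "",
        "| group | count | fraction |",
        "|---|---|---|",
    ]
    for g, c in report.group_counts.items():
        lines.append(f"| {g} | {c} | {report.group_fractions[g]:.2f} |")
    lines += [
        "",
        f"Mixed-context regulators (divergent + co-transcribed): {report.mixed_count}",
        f"Predicted targets at <= {report.threshold_bp} bp: {report.n_predicted}",
        "",
    ]
    if report.separation_histogram:
        lines += ["| separation (bp) | pairs |", "|---|---|"]
        lines += [f"| {k} | {v} |" for k, v in report.separation_histogram.items()]
        lines.append("")
    if report.regional_densities:
        lines += ["| region | regulators | per Mb |", "|---|---|---|"]
        lines += [
            f"| {r['name']} | {r['count']} | {r['per_mb_display']} |"
            for r in report.regional_densities
        ]
        lines.append("")
    return "\n".join(lines)


def _plot_histogram(report: SummaryReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(report.separation_histogram)
    values = list(report.separation_histogram.values())
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(values)), values, color="#336699")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_xlabel("intergenic separation (bp)")
    ax.set_ylabel("divergent pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
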