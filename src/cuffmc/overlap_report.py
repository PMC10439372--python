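"""Between-species overlap assessment and report rendering.

Compares human and chimpanzee muscle-force distributions output by the
Monte Carlo suite: interval-overlap flags on the {1, 25, 50, 75, 99}
percentile summaries, box-and-whisker style figures per muscle and support
instance, and sensitivity-matrix charts. "Functional overlap" is
operationalised here as: the human inner-50% band intersects the chimpanzee
1-99% range AND the human median does not exceed the entire chimpanzee
range; the underlying literature uses the notion qualitatively, so the
exact rule is this package's documented definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .monte_carlo import SuiteResult, percentile_frame, suite_to_frame
from .species_params import CUFF_OUTPUTS


@dataclass(frozen=True)
class PercentileSummary:
    output_name: str
    instance: str
    values: dict  # {1, 25, 50, 75, 99} -> force %


@dataclass(frozen=True)
class OverlapAssessment:
    output_name: str
    instance: str
    human_percentiles: dict
    chimp_percentiles: dict
    inner50_overlaps: bool
    range_overlaps: bool
    human_median_above_chimp_range: bool
    functional_overlap: bool


def _intervals_overlap(lo_a, hi_a, lo_b, hi_b) -> bool:
    return lo_a <= hi_b and lo_b <= hi_a


def assess_overlap(
    human: PercentileSummary, chimp: PercentileSummary
) -> OverlapAssessment:
    """Interval-overlap flags for one output and support instance."""
    if (human.output_name, human.instance) != (chimp.output_name, chimp.instance):
        raise ValueError(
            "mismatched summaries: "
            f"{(human.output_name, human.instance)} vs "
            f"{(chimp.output_name, chimp.instance)}"
        )
    h, c = human.values, chimp.values
    range_overlaps = _intervals_overlap(h[1], h[99], c[1], c[99])
    inner50 = _intervals_overlap(h[25], h[75], c[1], c[99])
    median_above = h[50] > c[99]
    return OverlapAssessment(
        output_name=human.output_name,
        instance=human.instance,
        human_percentiles=dict(h),
        chimp_percentiles=dict(c),
        inner50_overlaps=inner50,
        range_overlaps=range_overlaps,
        human_median_above_chimp_range=median_above,
        functional_overlap=inner50 and not median_above,
    )


def assess_suite(suite: SuiteResult) -> list[OverlapAssessment]:
    """All 21 per-(output, instance) overlap assessments of a full suite."""
    assessments = []
    instances = sorted({r.instance for r in suite.results})
    for instance in instances:
        for output in CUFF_OUTPUTS:
            h = suite.result("human", instance, output)
            c = suite.result("chimpanzee", instance, output)
            assessments.append(
                assess_overlap(
                    PercentileSummary(output, instance, h.cdf.percentiles),
                    PercentileSummary(output, instance, c.cdf.percentiles),
                )
            )
    return assessments


def overlap_table(assessments) -> pd.DataFrame:
    rows = []
    for a in assessments:
        row = {
            "output": a.output_name,
            "instance": a.instance,
            "inner50_overlaps": a.inner50_overlaps,
            "range_overlaps": a.range_overlaps,
            "human_median_above_chimp_range": a.human_median_above_chimp_range,
            "functional_overlap": a.functional_overlap,
        }
        row.update({f"human_p{p}": v for p, v in a.human_percentiles.items()})
        row.update({f"chimp_p{p}": v for p, v in a.chimp_percentiles.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _check_complete(suite: SuiteResult, species, instances) -> None:
    missing = []
    for s in species:
        for i in instances:
            for o in CUFF_OUTPUTS:
                try:
                    suite.result(s, i, o)
                except KeyError:
                    missing.append((s, i, o))
    if missing:
        raise ValueError(f"incomplete suite; missing triples: {missing}")


def render_reports(
    suite: SuiteResult,
    assessments,
    out_dir: str | Path,
    species=("human", "chimpanzee"),
    instances=("early_support", "mid_support", "late_support"),
) -> dict[str, Path]:
    """Write percentile figures, sensitivity charts and CSV tables.

    Produces one 7 x 3 panel figure of paired percentile boxes, one
    sensitivity chart per species (when sensitivities were computed), and
    machine-readable CSVs. Deterministic: touches no random state.
    """
    _check_complete(suite, species, instances)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    fig, axes = plt.subplots(
        len(CUFF_OUTPUTS), len(instances), figsize=(11, 16), sharex=True
    )
    colors = {"human": "tab:blue", "chimpanzee": "tab:orange"}
    for row, output in enumerate(CUFF_OUTPUTS):
        for col, instance in enumerate(instances):
            ax = axes[row][col]
            for k, s in enumerate(species):
                p = suite.result(s, instance, output).cdf.percentiles
                y = k
                ax.plot([p[1], p[99]], [y, y], color=colors.get(s, "k"), lw=1)
                ax.add_patch(
                    plt.Rectangle(
                        (p[25], y - 0.25),
                        max(p[75] - p[25], 1e-3),
                        0.5,
                        facecolor=colors.get(s, "k"),
                        alpha=0.4,
                    )
                )
                ax.plot([p[50], p[50]], [y - 0.25, y + 0.25], color="k", lw=1.5)
            ax.set_yticks(range(len(species)))
            ax.set_yticklabels(species if col == 0 else [""] * len(species), fontsize=7)
            ax.set_xlim(-2, 102)
            if row == 0:
                ax.set_title(instance, fontsize=9)
            if col == 0:
                ax.set_ylabel(output, fontsize=7)
    fig.suptitle("Rotator cuff force distributions (% max force)", fontsize=11)
    fig.tight_layout()
    path = out / "force_distributions.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written["force_distributions"] = path

    for s, matrix in suite.sensitivity.items():
        if matrix is None:
            continue
        fig, ax = plt.subplots(figsize=(8, 6))
        data = matrix.to_numpy(dtype=float)
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(matrix.columns)))
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(matrix.index)))
        ax.set_yticklabels(matrix.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="|S| (mean over levels, instances)")
        ax.set_title(f"{s}: input sensitivity of cuff force distributions")
        fig.tight_layout()
        path = out / f"sensitivity_{s}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written[f"sensitivity_{s}"] = path
        matrix.to_csv(out / f"sensitivity_{s}.csv")
        written[f"sensitivity_{s}_csv"] = out / f"sensitivity_{s}.csv"

    cdf_csv = out / "cdf_levels.csv"
    suite_to_frame(suite).to_csv(cdf_csv, index=False)
    written["cdf_levels"] = cdf_csv
    pct_csv = out / "percentile_summary.csv"
    percentile_frame(suite).to_csv(pct_csv, index=False)
    written["percentile_summary"] = pct_csv
    ov_csv = out / "overlap_table.csv"
    overlap_table(assessments).to_csv(ov_csv, index=False)
    written["overlap_table"] = ov_csv
    return written
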