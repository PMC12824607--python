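"""Protein "lollipop" visualization of cohort variants.

Each distinct protein-coding variant is drawn as a stem whose height and
marker area are proportional to its carrier count in the cohort, colored by
consequence class, over domain boxes drawn to scale from a local domain
table.  Non-coding and structural variants have no protein coordinate and
are skipped with a count note in the legend.  Output is deterministic SVG
(variants ordered by protein position, fixed hash salt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cohort import Cohort

_CONSEQUENCE_COLORS = {
    "missense_variant": "#1f77b4",
    "stop_gained": "#d62728",
    "frameshift_variant": "#ff7f0e",
    "start_lost": "#9467bd",
    "transcript_ablation": "#8c564b",
}
_DEFAULT_COLOR = "#7f7f7f"


@dataclass(frozen=True)
class DomainTable:
    """Protein domains as (name, start, end) rows, 1-based inclusive."""

    rows: tuple[tuple[str, int, int], ...]
    protein_length: int

    def __post_init__(self) -> None:
        for name, start, end in self.rows:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            if end > self.protein_length:
                raise ValueError(
                    f"domain {name} extends past protein length "
                    f"({end} > {self.protein_length})"
                )

    @classmethod
    def from_tsv(cls, path, protein_length: int) -> "DomainTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            rows=tuple(
                (str(r["domain"]), int(r["start"]), int(r["end"]))
                for _, r in df.iterrows()
            ),
            protein_length=protein_length,
        )


def lollipop_svg(
    cohort: Cohort, transcript: str, domains: DomainTable, out_path
) -> Path | None:
    """Render the cohort's protein variants for *transcript* as an SVG file.

    Returns the output path, or None (with a warning) when no variant has a
    protein coordinate.
    """
    counts: dict[tuple[int, str, str], int] = {}
    n_skipped = 0
    for ind in cohort:
        for v in ind.variants:
            if transcript and v.transcript and v.transcript != transcript:
                continue
            if v.protein_span is None or v.structural_kind is not None:
                n_skipped += 1
                continue
            pos = v.protein_span[0]
            consequence = min(v.consequences) if v.consequences else "other"
            counts[(pos, v.key, consequence)] = (
                counts.get((pos, v.key, consequence), 0) + v.allele_count
            )
    if not counts:
        import logging

        logging.getLogger(__name__).warning(
            "no displayable protein variants (skipped %d records)", n_skipped
        )
        return None

    plt.rcParams["svg.hashsalt"] = "phenogpc"
    fig, ax = plt.subplots(figsize=(9, 3))
    for name, start, end in domains.rows:
        ax.add_patch(
            plt.Rectangle(
                (start, -0.18), end - start + 1, 0.16, color="#cfe2f3", zorder=1
            )
        )
        ax.text(
            (start + end) / 2, -0.10, name, ha="center", va="center", fontsize=7
        )
    ax.plot(
        [1, domains.protein_length], [0, 0], color="black", lw=1.2, zorder=2
    )
    max_count = max(counts.values())
    for (pos, key, consequence), n in sorted(counts.items()):
        height = n / max_count
        color = _CONSEQUENCE_COLORS.get(consequence, _DEFAULT_COLOR)
        ax.plot([pos, pos], [0, height], color=color, lw=1.0, zorder=3)
        ax.scatter(
            [pos], [height], s=40 * n / max_count + 10, color=color, zorder=4,
            label=None,
        )
    handles = [
        plt.Line2D([], [], color=c, marker="o", ls="", label=lab)
        for lab, c in _CONSEQUENCE_COLORS.items()
        if any(k[2] == lab for k in counts)
    ]
    if n_skipped:
        handles.append(
            plt.Line2D(
                [], [], ls="", label=f"{n_skipped} non-coding/structural not shown"
            )
        )
    if handles:
        ax.legend(handles=handles, fontsize=7, loc="upper right")
    ax.set_xlim(0, domains.protein_length + 1)
    ax.set_ylim(-0.25, 1.2)
    ax.set_yticks([])
    ax.set_xlabel("protein residue")
    ax.set_title(transcript or "protein variants")
    out_path = Path(out_path)
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)
    return out_path
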