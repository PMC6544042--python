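"""Per-column conservation statistics and co-occurrence tables for the loop.

Frequencies are empirical per-column distributions over the 20 amino acids
for the seven window positions (labelled 31-37). Information content follows
the Schneider–Stephens sequence-logo convention:

    IC(col) = log2(20) - H(col) [- e(n)]      (bits)

with letter heights ``freq * IC`` and the optional small-sample correction
``e(n) = 19 / (2 ln 2 n)`` (floored at zero). Co-occurrence tables report,
per tip residue / loop type / enzyme flag, the count and the percentage of
loops carrying proline at the −2 position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AMINO_ACIDS

__all__ = [
    "FrequencyMatrix",
    "LogoMatrix",
    "column_frequencies",
    "information_content",
    "cooccurrence_table",
    "pool_frequency_matrices",
    "plot_logo",
]

_POSITIONS = list(range(31, 38))


@dataclass
class FrequencyMatrix:
    """Per-column amino-acid frequencies; rows = residues, columns = 31-37."""

    frequencies: pd.DataFrame
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        colsum = self.frequencies.sum(axis=0)
        if (np.abs(colsum - 1.0) > 1e-9).any():
            raise ValueError("frequency columns must sum to 1")


@dataclass
class LogoMatrix:
    """Letter heights in bits; per-column total = information content."""

    heights: pd.DataFrame
    information: pd.Series
    small_sample_correction: bool

    def __post_init__(self):
        if (self.information < -1e-12).any() or (self.information > np.log2(20) + 1e-12).any():
            raise ValueError("column information must be within [0, log2(20)]")


def column_frequencies(loops) -> FrequencyMatrix:
    """Empirical per-column residue frequencies over a set of loop windows."""
    loops = list(loops)
    if not loops:
        raise ValueError("need at least one loop")
    width = len(loops[0].loop_seq)
    positions = _POSITIONS if width == 7 else list(range(1, width + 1))
    counts = np.zeros((len(AMINO_ACIDS), width))
    for a in loops:
        if len(a.loop_seq) != width:
            raise ValueError("all loops must have equal window width")
        for col, aa in enumerate(a.loop_seq):
            if aa in AMINO_ACIDS:
                counts[AMINO_ACIDS.index(aa), col] += 1
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    freqs = pd.DataFrame(counts / totals, index=list(AMINO_ACIDS), columns=positions)
    return FrequencyMatrix(frequencies=freqs, n=len(loops))


def information_content(freqs: FrequencyMatrix, small_sample_correction: bool = False) -> LogoMatrix:
    """Information-content logo matrix (bits) from a frequency matrix."""
    f = freqs.frequencies.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=0)
    ic = np.log2(20) - entropy
    if small_sample_correction:
        ic = ic - 19.0 / (2.0 * np.log(2) * freqs.n)
    ic = np.clip(ic, 0.0, None)
    heights = pd.DataFrame(
        f * ic[np.newaxis, :], index=freqs.frequencies.index, columns=freqs.frequencies.columns
    )
    information = pd.Series(ic, index=freqs.frequencies.columns)
    return LogoMatrix(heights=heights, information=information, small_sample_correction=small_sample_correction)


def pool_frequency_matrices(matrices) -> FrequencyMatrix:
    """Count-weighted pooling of subset frequency matrices (exact identity
    with the frequencies of the pooled loop set)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    n = sum(m.n for m in matrices)
    pooled = sum(m.frequencies * m.n for m in matrices) / n
    return FrequencyMatrix(frequencies=pooled, n=n)


def _round_half_up(x: float, decimals: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cooccurrence_table(
    classes,
    annotations: pd.DataFrame = None,
    group_by: str = "tip_residue",
    genome_of: dict = None,
) -> pd.DataFrame:
    """Count / P32-percentage table grouped by tip residue, type, or enzyme.

    ``group_by`` is one of ``tip_residue``, ``loop_type``, ``enzyme``. The
    enzyme grouping needs ``annotations`` (per-genome flags) and ``genome_of``
    mapping protein_id -> genome_id. Percentages are reported half-up rounded
    to 2 decimals alongside the unrounded value.
    """
    classes = list(classes)
    if group_by not in ("tip_residue", "loop_type", "enzyme"):
        raise ValueError(f"unknown group_by {group_by!r}")

    def row(key, members):
        n = len(members)
        with_p = sum(1 for c in members if c.has_P_minus2)
        pct = 100.0 * with_p / n if n else 0.0
        out = {
            "group": key,
            "count": n,
            "pct_P32": _round_half_up(pct),
            "pct_P32_unrounded": pct,
        }
        if annotations is not None and genome_of is not None and group_by != "enzyme":
            genomes = {genome_of[c.protein_id] for c in members if c.protein_id in genome_of}
            sub = annotations[annotations["genome_id"].isin(genomes)]
            denom = max(len(sub), 1)
            for enz in ("epmA", "epmC", "earP", "dhs"):
                if enz in sub.columns:
                    out[f"pct_{enz}"] = _round_half_up(100.0 * float(sub[enz].astype(bool).sum()) / denom)
        return out

    rows = []
    if group_by in ("tip_residue", "loop_type"):
        keyfun = (
            (lambda c: c.loop_type.replace("other(", "")[:1] if c.loop_type.startswith("other") else
             ("K" if c.loop_type == "lysine-type" else "R"))
            if group_by == "tip_residue"
            else (lambda c: c.loop_type)
        )
        groups: dict = {}
        for c in classes:
            groups.setdefault(keyfun(c), []).append(c)
        for key in sorted(groups, key=lambda k: (-len(groups[k]), k)):
            rows.append(row(key, groups[key]))
    else:
        if annotations is None or genome_of is None:
            raise ValueError("enzyme grouping requires annotations and genome_of")
        missing = [c.protein_id for c in classes if c.protein_id not in genome_of]
        if missing:
            raise ValueError(f"proteins without a genome mapping: {missing[:3]}...")
        flag_of = {
            enz: set(annotations.loc[annotations[enz].astype(bool), "genome_id"])
            for enz in ("epmA", "epmC", "earP", "dhs")
            if enz in annotations.columns
        }
        for enz, genomes in flag_of.items():
            members = [c for c in classes if genome_of[c.protein_id] in genomes]
            if members:
                rows.append(row(enz, members))
    return pd.DataFrame(rows)


def plot_logo(logo: LogoMatrix, path=None, ax=None, colors: dict = None):
    """Render a basic information-content sequence logo with matplotlib.

    Letters are drawn as text paths stretched to their height in bits and
    stacked smallest-to-largest per column.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    default_colors = {
        **{aa: "#2c7fb8" for aa in "ACFGILMPVW"},
        **{aa: "#d95f02" for aa in "KRH"},
        **{aa: "#1b9e77" for aa in "DE"},
        **{aa: "#7570b3" for aa in "NQSTY"},
    }
    colors = colors or default_colors
    font = FontProperties(family="DejaVu Sans", weight="bold")

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(0.9 * len(logo.heights.columns) + 1, 3))
    for x, col in enumerate(logo.heights.columns):
        y = 0.0
        column = logo.heights[col]
        for aa, h in column[column > 1e-9].sort_values().items():
            tp = TextPath((0, 0), aa, size=1.0, prop=font)
            bb = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(x + 0.05, y)
            )
            ax.add_patch(PathPatch(tp.transformed(transform), facecolor=colors.get(aa, "black"), edgecolor="none"))
            y += h
    ax.set_xlim(-0.2, len(logo.heights.columns) + 0.2)
    ax.set_ylim(0, max(np.log2(20), float(logo.information.max()) + 0.2))
    ax.set_xticks([i + 0.5 for i in range(len(logo.heights.columns))])
    ax.set_xticklabels(logo.heights.columns)
    ax.set_ylabel("bits")
    ax.set_xlabel("reference position")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        if own_fig:
            plt.close(ax.figure)
    return ax
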