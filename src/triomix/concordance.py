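"""Cross-technology comparison: Venn partition of detected genes,
per-region abundance summaries, discordant-category annotation and
Spearman rank concordance under successive exclusion rules.

The three exclusion rule sets mirror the analysis progression of
mRNA/protein comparisons: (a) all co-detected genes; (b) dropping rows
flagged as multi-gene mappings (one protein or probe matching several
genes); (c) additionally dropping three biologically discordant
categories — ribosomal genes (GO cellular component *ribosome*), histones
and vitellogenins (keyword match on the gene description).  Because the
categories are discordant by biology (maternal protein deposition, poly-A
depletion, untranslated RNA function), each exclusion step should raise the
rank correlation between transcript and protein signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("MS∩RNA∩ARR", "MS∩RNA", "MS∩ARR", "RNA∩ARR", "MS-only", "RNA-only", "ARR-only")
RULE_SETS = ("all", "drop_multi", "drop_multi_and_categories")
CATEGORY_NAMES = ("ribosomal", "histone", "vitellogenin")
RIBOSOME_GO_CC = "GO:0005840"

_TECH_SHORT = {"proteomics": "MS", "rnaseq": "RNA", "array": "ARR"}


@dataclass
class VennPartition:
    """Disjoint assignment of every detected gene to one of 7 overlap regions."""

    region_of: dict[str, str]
    region_sizes: dict[str, int]
    unannotated: dict[str, int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(self.region_of)


@dataclass
class ConcordanceResult:
    pair: tuple[str, str]
    rule_set: str
    rho: float  # NaN when undefined (zero rank variance)
    n: int
    low_n: bool = False


def venn_partition(
    detected: dict[str, set[str]], unannotated: dict[str, int] | None = None
) -> VennPartition:
    """Partition the union of detected genes into the 7 disjoint regions.

    ``detected`` maps technology name (proteomics, rnaseq, array) to its
    detected gene set.
    """
    ms = detected.get("proteomics", set())
    rna = detected.get("rnaseq", set())
    arr = detected.get("array", set())
    region_of: dict[str, str] = {}
    for g in ms | rna | arr:
        key = (g in ms, g in rna, g in arr)
        region_of[g] = {
            (True, True, True): "MS∩RNA∩ARR",
            (True, True, False): "MS∩RNA",
            (True, False, True): "MS∩ARR",
            (False, True, True): "RNA∩ARR",
            (True, False, False): "MS-only",
            (False, True, False): "RNA-only",
            (False, False, True): "ARR-only",
        }[key]
    sizes = {r: 0 for r in REGIONS}
    for r in region_of.values():
        sizes[r] += 1
    return VennPartition(region_of, sizes, dict(unannotated or {}))


def five_number(values: np.ndarray) -> dict[str, float]:
    """Min, quartiles (linear interpolation of order statistics), max."""
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return dict(zip(("min", "q1", "median", "q3", "max"), map(float, q)))


def region_summaries(partition: VennPartition, unified: pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-technology five-number summaries of log2 values.

    Counts (spectral and read) get a pseudo-value of 0.5 before log2 so
    zero-adjacent values stay finite; array intensities are logged as-is.
    Region/technology combinations without values are omitted.
    """
    region = unified["gene_id"].map(partition.region_of)
    rows = []
    for tech in ("proteomics", "rnaseq", "array"):
        vals = unified[f"{tech}_value"]
        logged = np.log2(vals + 0.5) if tech != "array" else np.log2(vals)
        for reg in REGIONS:
            sel = logged[(region == reg) & vals.notna()]
            if len(sel) == 0:
                continue
            summary = five_number(sel.to_numpy())
            rows.append({"region": reg, "technology": tech, "n": len(sel), **summary})
    return pd.DataFrame(rows)


def annotate_categories(
    gene_info: pd.DataFrame,
    ribosome_go_term: str = RIBOSOME_GO_CC,
    histone_keyword: str = "histone",
    vitellogenin_keyword: str = "vitellogenin",
) -> pd.Series:
    """Label genes ribosomal / histone / vitellogenin / none.

    Ribosomal wins by GO cellular-component membership; the other two are
    case-insensitive keyword matches on the description.  Precedence on
    conflict: ribosomal > histone > vitellogenin.

    ``gene_info`` is indexed by gene_id with columns description and
    go_cc_terms (semicolon-joined).  Returns a gene_id-indexed Series.
    """
    desc = gene_info["description"].fillna("").str.lower()
    go = gene_info["go_cc_terms"].fillna("")
    is_rib = go.str.split(";").map(lambda terms: ribosome_go_term in terms)
    is_his = desc.str.contains(histone_keyword.lower(), regex=False)
    is_vit = desc.str.contains(vitellogenin_keyword.lower(), regex=False)
    label = pd.Series("none", index=gene_info.index, dtype=object)
    label[is_vit] = "vitellogenin"
    label[is_his] = "histone"
    label[is_rib] = "ribosomal"
    return label


def spearman(x, y) -> float:
    """Spearman's rho: product-moment correlation of midranks.

    Equals ``1 - 6 * sum(d^2) / (n (n^2 - 1))`` on tie-free data.  Returns
    NaN (undefined) when either vector has zero rank variance; requires
    paired complete observations of equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError(f"spearman requires n >= 3, got n = {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("spearman requires complete paired observations (no NaN)")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def plot_comparison(
    unified: pd.DataFrame,
    categories: pd.Series,
    path: str,
    pair: tuple[str, str] = ("rnaseq", "proteomics"),
) -> None:
    """Scatter the co-detected genes of one technology pair (log2 axes).

    Category outliers are colored (ribosomal red, histone blue, vitellogenin
    green); multi-gene mappings are drawn as crosses.  Written as PNG/SVG
    according to the file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = pair
    sel = unified.loc[unified[f"{a}_detected"] & unified[f"{b}_detected"]].copy()
    cat = sel["gene_id"].map(categories).fillna("none")
    x = np.log2(sel[f"{a}_value"] + 0.5)
    y = np.log2(sel[f"{b}_value"] + 0.5)
    colors = {"none": "0.6", "ribosomal": "red", "histone": "blue", "vitellogenin": "green"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, color in colors.items():
        m = (cat == name) & ~sel["multi_gene"]
        ax.scatter(x[m], y[m], s=8, c=color, label=name if name != "none" else None, alpha=0.6)
        mx = (cat == name) & sel["multi_gene"]
        ax.scatter(x[mx], y[mx], s=14, c=color, marker="x", alpha=0.6)
    rho = spearman(sel[f"{a}_value"], sel[f"{b}_value"]) if len(sel) >= 3 else float("nan")
    ax.set_xlabel(f"log2 {a} signal")
    ax.set_ylabel(f"log2 {b} signal")
    ax.set_title(f"rho = {rho:.2f} (n = {len(sel)}); crosses = multi-gene matches")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def concordance_with_exclusions(
    unified: pd.DataFrame,
    categories: pd.Series,
    universe: str = "triple",
    min_n: int = 10,
) -> list[ConcordanceResult]:
    """Spearman rho per technology pair under the three exclusion rule sets.

    ``universe`` selects the comparison set: ``"triple"`` restricts every
    pair to genes detected by all three technologies; ``"pairwise"`` uses
    genes co-detected by the pair at hand.  ``categories`` is a
    gene_id-indexed Series from :func:`annotate_categories`.  Results with
    fewer than ``min_n`` genes are flagged low-n.
    """
    if universe not in ("triple", "pairwise"):
        raise ValueError(f"universe must be 'triple' or 'pairwise', got {universe!r}")
    cat = unified["gene_id"].map(categories).fillna("none")
    triple = unified[[f"{t}_detected" for t in ("proteomics", "rnaseq", "array")]].all(axis=1)

    results = []
    for pair in combinations(("proteomics", "rnaseq", "array"), 2):
        a, b = pair
        co = unified[f"{a}_detected"] & unified[f"{b}_detected"]
        base = triple if universe == "triple" else co
        masks = {
            "all": base,
            "drop_multi": base & ~unified["multi_gene"],
            "drop_multi_and_categories": base & ~unified["multi_gene"] & cat.eq("none"),
        }
        for rule in RULE_SETS:
            sel = unified.loc[masks[rule]]
            n = len(sel)
            rho = (
                spearman(sel[f"{a}_value"], sel[f"{b}_value"]) if n >= 3 else float("nan")
            )
            results.append(ConcordanceResult(pair=pair, rule_set=rule, rho=rho, n=n, low_n=n < min_n))
    return results
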