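"""Two-color microarray processing: background correction, within-array
loess normalization on the MA representation, between-array quantile
normalization, and probe-to-gene collapse.

M = log2(Cy5/Cy3) and A = (log2 Cy5 + log2 Cy3)/2 are computed from
background-corrected channels (subtraction with a small positive floor so
logs stay finite).  Loess removes the intensity-dependent dye bias within
each array by subtracting a robust locally weighted linear fit of M on A;
quantile normalization then forces all arrays to share one intensity
distribution.  The per-gene expression value is the linear-scale intensity
``2**A`` collapsed over probes and arrays, a monotone function of signal —
sufficient for the rank statistics downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

BACKGROUND_FLOOR = 0.5


def background_correct(probes: pd.DataFrame, floor: float = BACKGROUND_FLOOR) -> pd.DataFrame:
    """Subtract per-probe background from each channel, flooring at ``floor``.

    Returns a copy with ``cy3`` and ``cy5`` columns of corrected intensities.
    """
    out = probes.copy()
    out["cy3"] = np.maximum(probes["fg_cy3"] - probes["bg_cy3"], floor)
    out["cy5"] = np.maximum(probes["fg_cy5"] - probes["bg_cy5"], floor)
    return out


def compute_ma(corrected: pd.DataFrame) -> pd.DataFrame:
    """M/A representation of background-corrected two-channel intensities."""
    out = corrected.copy()
    l3 = np.log2(corrected["cy3"])
    l5 = np.log2(corrected["cy5"])
    out["M"] = l5 - l3
    out["A"] = 0.5 * (l5 + l3)
    return out


def loess_normalize_within(
    ma: pd.DataFrame, span: float = 0.3, iterations: int = 3
) -> pd.DataFrame:
    """Remove the intensity-dependent dye trend within each array.

    For every array, fits a robust locally weighted linear regression
    (tricube weights, ``span`` fraction of points, ``iterations``
    robustifying reweights) of M on A and subtracts it: ``M_norm = M -
    fit(A)``.  A is unchanged.  Arrays whose A values have zero spread get
    the global mean of M subtracted instead.
    """
    out = ma.copy()
    m_norm = np.empty(len(ma))
    for _, idx in ma.groupby("array_id", sort=False).indices.items():
        a = ma["A"].to_numpy()[idx]
        m = ma["M"].to_numpy()[idx]
        if len(idx) < 10:
            raise ValueError(f"loess normalization needs >= 10 probes per array, got {len(idx)}")
        if np.ptp(a) == 0.0:
            fit = np.full_like(m, m.mean())
        else:
            delta = 0.005 * np.ptp(a)  # fast interpolation between close x-values
            fit = lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=False)
        m_norm[idx] = m - fit
    out["M"] = m_norm
    return out


def quantile_normalize_between(values: pd.DataFrame) -> pd.DataFrame:
    """Force all arrays (columns) to share one value distribution.

    The value at rank *k* in each column is replaced by the mean over
    columns of their rank-*k* values; tied entries receive the mean of the
    quantile slots the tie covers.  A single column is returned unchanged.
    Rows must be complete (no missing values).
    """
    if values.isna().any().any():
        raise ValueError("quantile normalization requires complete rows (no missing values)")
    mat = values.to_numpy(dtype=float)
    n, k = mat.shape
    if k <= 1 or n == 0:
        return values.copy()
    sorted_means = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(k):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = sorted_means
        # ties: average the slot values the tied group covers
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_to_genes: dict[str, set[str]],
    probe_stat: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-(probe, array) values to one expression value per gene.

    Per (gene, array) the ``probe_stat`` (median by default; mean/max
    available) is taken over the gene's mapped probes, then averaged over
    arrays.  Probes without a gene mapping are tallied per array into an
    unannotated bin; probes mapping to several genes contribute to each and
    flag those genes ``multi_gene``.

    Parameters
    ----------
    probe_values : table with columns probe_id, array_id, value.
    probe_to_genes : total mapping probe_id -> set of gene_ids (may be empty).

    Returns ``(gene rows with columns gene_id, value, multi_gene;
    per-array unannotated tallies with columns array_id, n_unannotated)``.
    """
    if probe_stat not in ("median", "mean", "max"):
        raise ValueError(f"probe_stat must be median, mean or max, got {probe_stat!r}")
    lookup = {
        p: sorted(probe_to_genes.get(p, ())) for p in probe_values["probe_id"].unique()
    }
    genes_of = probe_values["probe_id"].map(lookup)
    n_map = genes_of.map(len).to_numpy()

    unann = (
        probe_values.loc[n_map == 0]
        .groupby("array_id", sort=True)
        .size()
        .rename("n_unannotated")
        .reset_index()
    )
    # make sure every array appears in the tally, even with zero unannotated
    all_arrays = pd.DataFrame({"array_id": sorted(probe_values["array_id"].unique())})
    unann = all_arrays.merge(unann, on="array_id", how="left").fillna({"n_unannotated": 0})
    unann["n_unannotated"] = unann["n_unannotated"].astype(int)

    mapped = probe_values.loc[n_map > 0]
    if len(mapped) == 0:
        return pd.DataFrame(columns=["gene_id", "value", "multi_gene"]), unann
    expanded = pd.DataFrame(
        {
            "gene_id": np.concatenate(genes_of[n_map > 0].to_numpy()),
            "array_id": np.repeat(mapped["array_id"].to_numpy(), n_map[n_map > 0]),
            "value": np.repeat(mapped["value"].to_numpy(), n_map[n_map > 0]),
            "multi": np.repeat(n_map[n_map > 0] > 1, n_map[n_map > 0]),
        }
    )
    per_array = expanded.groupby(["gene_id", "array_id"], sort=True).agg(
        value=("value", probe_stat), multi=("multi", "any")
    )
    per_gene = per_array.groupby("gene_id", sort=True).agg(
        value=("value", "mean"), multi_gene=("multi", "any")
    )
    return per_gene.reset_index(), unann


def array_expression(
    probes: pd.DataFrame,
    probe_to_genes: dict[str, set[str]],
    span: float = 0.3,
    probe_stat: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full array stage: background -> MA -> loess -> quantile -> collapse.

    Returns the per-gene expression table (``gene_id, value, multi_gene``;
    value is linear-scale normalized intensity) and the per-array
    unannotated-probe tallies.
    """
    ma = compute_ma(background_correct(probes))
    ma = loess_normalize_within(ma, span=span)
    wide = ma.pivot(index="probe_id", columns="array_id", values="A")
    wide = quantile_normalize_between(wide)
    long = wide.reset_index().melt(id_vars="probe_id", var_name="array_id", value_name="A")
    long["value"] = np.exp2(long["A"])
    gene_rows, unann = collapse_probes(long, probe_to_genes, probe_stat=probe_stat)
    return gene_rows, unann
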