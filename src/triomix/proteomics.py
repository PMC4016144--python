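"""Spectral-counting proteomics quantification.

Peptide-spectrum matches (PSMs) arrive with identification probabilities
from upstream statistical validation; this module applies a dual acceptance
criterion — a minimum probability and a global target-decoy FDR — then
counts accepted spectra per protein (spectral counting) and expands protein
groups to individual proteins so they can be mapped to genes.

The decoy-based FDR estimate is ``decoys accepted / targets accepted``,
the convention for a concatenated equal-size decoy database.  A
model-based estimate, the mean of ``1 - p`` over accepted targets, is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FdrEstimate:
    """FDR bookkeeping at the chosen acceptance threshold."""

    threshold: float
    n_target_accepted: int
    n_decoy_accepted: int
    fdr_decoy: float
    fdr_model: float


def _split_proteins(s: str) -> list[str]:
    return [p for p in str(s).split(";") if p]


def filter_psms(
    psms: pd.DataFrame, min_probability: float = 0.95, max_fdr: float = 0.01
) -> tuple[pd.DataFrame, FdrEstimate]:
    """Accept target PSMs above the smallest threshold meeting both criteria.

    The threshold ``t*`` is the smallest value ``>= min_probability`` (among
    ``min_probability`` itself and the distinct observed probabilities above
    it) at which the decoy-based FDR of PSMs with probability ``>= t`` drops
    to ``max_fdr`` or below.  Decoys are used for estimation only and are
    excluded from the returned accepted set.

    Returns ``(accepted_targets, FdrEstimate)``.  An empty input yields an
    empty result with zero counts.  If no threshold achieves ``max_fdr`` a
    ``ValueError`` reports the best achievable FDR.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError(f"min_probability must be in [0, 1], got {min_probability}")
    if not 0.0 < max_fdr <= 1.0:
        raise ValueError(f"max_fdr must be in (0, 1], got {max_fdr}")
    if len(psms) == 0:
        return psms.copy(), FdrEstimate(min_probability, 0, 0, 0.0, 0.0)

    prob = psms["probability"].to_numpy(dtype=float)
    is_decoy = psms["is_decoy"].to_numpy().astype(bool)

    candidates = np.unique(np.concatenate([[min_probability], prob[prob >= min_probability]]))
    # counts of targets/decoys with probability >= t, for each candidate t
    order_t = np.sort(prob[~is_decoy])
    order_d = np.sort(prob[is_decoy])
    n_t = len(order_t) - np.searchsorted(order_t, candidates, side="left")
    n_d = len(order_d) - np.searchsorted(order_d, candidates, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), 0.0)

    ok = fdr <= max_fdr
    if not ok.any():
        raise ValueError(
            f"no probability threshold >= {min_probability} achieves FDR <= {max_fdr}; "
            f"best achievable is {fdr.min():.4f}"
        )
    i = int(np.argmax(ok))  # candidates ascending -> first True is smallest t*
    t_star = float(candidates[i])

    accept = (~is_decoy) & (prob >= t_star)
    accepted = psms.loc[accept].copy()
    n_acc = int(accept.sum())
    fdr_model = float((1.0 - prob[accept]).mean()) if n_acc else 0.0
    est = FdrEstimate(
        threshold=t_star,
        n_target_accepted=n_acc,
        n_decoy_accepted=int(n_d[i]),
        fdr_decoy=float(fdr[i]),
        fdr_model=fdr_model,
    )
    return accepted, est


def spectral_count(accepted_psms: pd.DataFrame) -> pd.DataFrame:
    """Count accepted spectra per protein (group-expanded).

    Every PSM contributes one count to *each* protein in its group, so
    group counts are preserved under later expansion to genes.
    ``unique_peptides`` counts distinct peptide strings observed in
    single-protein groups only (peptides that identify the protein
    unambiguously); ``shared_flag`` marks proteins supported by at least one
    multi-protein-group PSM.

    Returns columns ``protein_id, spectral_count, unique_peptides, shared_flag``.
    """
    cols = ["protein_id", "spectral_count", "unique_peptides", "shared_flag"]
    if len(accepted_psms) == 0:
        return pd.DataFrame(columns=cols)
    groups = accepted_psms["proteins"].map(_split_proteins)
    sizes = groups.map(len).to_numpy()
    flat = pd.DataFrame(
        {
            "protein_id": np.concatenate(groups.to_numpy()),
            "peptide": np.repeat(accepted_psms["peptide"].to_numpy(), sizes),
            "shared": np.repeat(sizes > 1, sizes),
        }
    )
    agg = flat.groupby("protein_id", sort=True).agg(
        spectral_count=("protein_id", "size"), shared_flag=("shared", "any")
    )
    uniq = (
        flat.loc[~flat["shared"]]
        .groupby("protein_id", sort=True)["peptide"]
        .nunique()
        .rename("unique_peptides")
    )
    out = agg.join(uniq).fillna({"unique_peptides": 0}).reset_index()
    out["unique_peptides"] = out["unique_peptides"].astype(int)
    return out[cols]


def expand_groups(
    protein_quants: pd.DataFrame, protein_to_genes: dict[str, set[str]]
) -> tuple[pd.DataFrame, int]:
    """Map protein-level counts onto genes, flagging ambiguous origins.

    Each protein row becomes one row per mapped gene, carrying the protein's
    full spectral count (abundance is not split across genes; downstream
    rank statistics treat multi-gene rows separately via the flag).  A row
    is flagged ``multi_gene`` when its protein maps to more than one gene or
    was itself supported by shared (multi-protein-group) spectra.  Proteins
    with no gene mapping are tallied, not dropped silently.

    Returns ``(gene rows with columns gene_id, value, multi_gene, n_unmapped_proteins)``.
    """
    if len(protein_quants) == 0:
        return pd.DataFrame(columns=["gene_id", "value", "multi_gene"]), 0
    genes_of = protein_quants["protein_id"].map(
        lambda p: sorted(protein_to_genes.get(p, ()))
    )
    n_map = genes_of.map(len).to_numpy()
    unmapped = int((n_map == 0).sum())
    mapped = n_map > 0
    if not mapped.any():
        return pd.DataFrame(columns=["gene_id", "value", "multi_gene"]), unmapped
    multi = (n_map > 1) | protein_quants["shared_flag"].to_numpy(dtype=bool)
    out = pd.DataFrame(
        {
            "gene_id": np.concatenate(genes_of[mapped].to_numpy()),
            "value": np.repeat(
                protein_quants["spectral_count"].to_numpy(dtype=float)[mapped], n_map[mapped]
            ),
            "multi_gene": np.repeat(multi[mapped], n_map[mapped]),
        }
    )
    return out, unmapped
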