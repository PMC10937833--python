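"""Latent-variable ↔ signature association scoring by gene hold-out.

A positive entry U[s,k] only says the optimizer used signature s to shape
LV k.  To measure whether the association is real, the decomposition is
re-fit with one-fifth of each signature's genes masked out of the prior
matrix; if the LV truly captures the signature, the masked (held-out)
genes should still receive large loadings.  The association strength is
the AUC — the probability that a held-out gene gets a larger loading than
a gene outside the signature — with a one-sided Mann–Whitney p-value and
Benjamini–Hochberg FDR across all scored pairs.  An LV is called
interpretable when some signature passes AUC > 0.7 and FDR < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import NON_ASSOCIATED, ExpressionMatrix, PriorMatrix, SignatureAtlas
from .lv_stats import bh_adjust, mann_whitney
from .plier import PlierDecomposition, PlierModel

logger = logging.getLogger(__name__)

AUC_THRESHOLD = 0.7
FDR_THRESHOLD = 0.05


def holdout_auc(heldout, nonmembers):
    """AUC = P(held-out loading > non-member loading), ties counted one half,
    with the one-sided Mann–Whitney p-value for AUC > 0.5."""
    heldout = np.asarray(heldout, dtype=float)
    nonmembers = np.asarray(nonmembers, dtype=float)
    u, p = mann_whitney(heldout, nonmembers, alternative="greater")
    return u / (heldout.size * nonmembers.size), p


@dataclass
class AssociationRecord:
    lv: str
    signature: str
    u_weight: float
    auc: float
    p_value: float
    fdr: float = math.nan
    cell_type: str = NON_ASSOCIATED

    @property
    def passes(self) -> bool:
        return self.auc > AUC_THRESHOLD and self.fdr < FDR_THRESHOLD


@dataclass
class AssociationTable:
    records: list = field(default_factory=list)

    @property
    def interpretable_lvs(self) -> set:
        return select_interpretable(self)

    def to_frame(self) -> pd.DataFrame:
        interp = self.interpretable_lvs
        rows = [
            {
                "lv": r.lv,
                "signature": r.signature,
                "u_weight": r.u_weight,
                "auc": r.auc,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "cell_type": r.cell_type,
                "interpretable": r.lv in interp,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lv", "signature", "u_weight", "auc",
                "p_value", "fdr", "cell_type", "interpretable",
            ],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationTable":
        records = [
            AssociationRecord(
                lv=str(r.lv), signature=str(r.signature), u_weight=float(r.u_weight),
                auc=float(r.auc), p_value=float(r.p_value), fdr=float(r.fdr),
                cell_type=str(r.cell_type),
            )
            for r in df.itertuples()
        ]
        return cls(records)


def _resolve_config(config) -> dict:
    if isinstance(config, PlierModel):
        config = config.config
    valid = PlierDecomposition().get_params()
    return {k: v for k, v in config.items() if k in valid}


def _mask_prior(C: PriorMatrix, holdout_frac: float, rng) -> tuple:
    """Zero ⌈holdout_frac·|genes|⌉ member genes per signature.  Signatures
    with fewer than 5 member genes are left intact and excluded from
    scoring (a meaningful held-out/held-in split needs a few genes)."""
    masked = C.values.copy()
    heldout: dict = {}
    skipped = []
    for j, name in enumerate(C.signature_names):
        members = np.flatnonzero(C.values[:, j] > 0)
        if members.size < 5:
            skipped.append(name)
            continue
        n_hold = math.ceil(holdout_frac * members.size)
        chosen = rng.choice(members, size=n_hold, replace=False)
        masked[chosen, j] = 0.0
        heldout[name] = np.sort(chosen)
    if skipped:
        logger.warning(
            "%d signatures have <5 genes in the universe and were not scored: %s",
            len(skipped), skipped[:5],
        )
    return masked, heldout


def association_scan(
    Y: ExpressionMatrix,
    C: PriorMatrix,
    config,
    holdout_frac: float = 0.2,
    seed: int = 0,
    replicates: int = 1,
    cell_types=None,
    include_zero_weight: bool = False,
) -> AssociationTable:
    """Score every (LV, signature) pair with positive signature weight.

    The decomposition is re-fit with the training hyperparameters but a
    masked prior matrix; each signature's held-out genes are compared with
    all genes outside the signature on the LV's loading column.  With
    ``replicates`` > 1 the scan repeats with fresh hold-out draws and the
    per-pair AUCs/p-values are aggregated (mean AUC, median p).

    ``cell_types`` maps signature name → cell-type label (a SignatureAtlas
    also works); unknown signatures get "Non associated".

    ``include_zero_weight=True`` scores *all* (LV, signature) pairs, not
    only those the sparse U actually uses — a calibration diagnostic: for
    signatures unrelated to any LV the hold-out AUC should sit near 0.5.
    """
    if isinstance(cell_types, SignatureAtlas):
        cell_types = {s.name: s.cell_type for s in cell_types}
    cell_types = cell_types or {}
    params = _resolve_config(config)
    gene_order = list(Y.genes)
    if gene_order != list(C.genes):
        raise ValueError("expression and prior matrices must share gene order")

    per_pair: dict = {}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        masked, heldout = _mask_prior(C, holdout_frac, rng)
        est = PlierDecomposition(
            prior=pd.DataFrame(masked, index=C.genes, columns=C.signature_names),
            **params,
        )
        est.fit(Y.to_frame().T)
        Z = est.loadings_
        U = est.signature_weights_
        sig_index = {name: j for j, name in enumerate(est.signature_names_)}
        for name, hold_idx in heldout.items():
            j = sig_index.get(name)
            if j is None:
                continue
            members = C.values[:, list(C.signature_names).index(name)] > 0
            nonmember_idx = np.flatnonzero(~members)
            lvs = range(U.shape[1]) if include_zero_weight else np.flatnonzero(U[j] > 0)
            for k in lvs:
                auc, p = holdout_auc(Z[hold_idx, k], Z[nonmember_idx, k])
                key = (est.lv_names_[k], name)
                per_pair.setdefault(key, []).append((float(U[j, k]), auc, p))

    records = []
    for (lv, name), vals in sorted(per_pair.items()):
        u_w = float(np.mean([v[0] for v in vals]))
        auc = float(np.mean([v[1] for v in vals]))
        p = float(np.median([v[2] for v in vals]))
        records.append(
            AssociationRecord(
                lv=lv, signature=name, u_weight=u_w, auc=auc, p_value=p,
                cell_type=cell_types.get(name, NON_ASSOCIATED),
            )
        )
    if records:
        for r, q in zip(records, bh_adjust([r.p_value for r in records])):
            r.fdr = float(q)
    return AssociationTable(records)


def select_interpretable(table: AssociationTable) -> set:
    """LVs with at least one signature at AUC > 0.7 and FDR < 0.05 (strict)."""
    return {r.lv for r in table.records if r.passes}


def label_lvs(table: AssociationTable, atlas: SignatureAtlas | None = None) -> dict:
    """Label each interpretable LV with a cell-type category.

    The label comes from the passing record with the highest AUC (ties
    broken by lower FDR, then higher signature weight); LVs whose passing
    signatures are all "Non associated" are labelled "Rest".
    """
    lookup = {s.name: s.cell_type for s in atlas} if atlas is not None else None
    labels: dict = {}
    best: dict = {}
    for r in table.records:
        if not r.passes:
            continue
        key = (-r.auc, r.fdr, -r.u_weight)
        if r.lv not in best or key < best[r.lv][0]:
            cell_type = lookup.get(r.signature, r.cell_type) if lookup else r.cell_type
            best[r.lv] = (key, cell_type)
    for lv, (_, cell_type) in best.items():
        labels[lv] = "Rest" if cell_type == NON_ASSOCIATED else cell_type
    return labels
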