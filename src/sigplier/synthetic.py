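"""Synthetic expression data with planted signature-aligned latent structure.

The generator emulates the statistical structure the decomposition
assumes on the log2(TPM+0.5) scale: a handful of latent factors whose
gene loadings are supported on known signature gene sets, sample scores
with group-dependent shifts on some factors, and additive Gaussian noise.
It deliberately does not model RNA-seq count noise, library-size effects
or batch structure — it exists so that factor recovery, association
scoring, differential testing and classification are all testable against
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    LOG2_TPM_HALF,
    ExpressionMatrix,
    Signature,
    SignatureAtlas,
)

#: cell-type labels cycled over the planted (active) signatures
_ACTIVE_CELL_TYPES = ("PT", "ST", "End", "Ly", "My")


@dataclass
class SyntheticTruth:
    """Planted ground truth: loadings, scores, active pairs and shifts."""

    Z_true: np.ndarray  # genes × n_active
    B_true: np.ndarray  # n_active × samples
    active_signatures: list  # (signature_name, lv_index) pairs
    differential_lvs: list  # (lv_index, effect_size) pairs
    noise_sd: float
    seed: int

    @property
    def lv_scores(self) -> pd.DataFrame:
        names = [f"trueLV{i + 1}" for i in range(self.B_true.shape[0])]
        cols = [f"S{j + 1:03d}" for j in range(self.B_true.shape[1])]
        return pd.DataFrame(self.B_true, index=names, columns=cols)


def simulate_dataset(
    n_genes: int = 2000,
    n_samples: int = 80,
    n_signatures: int = 30,
    signature_size: int = 50,
    n_active: int = 5,
    n_differential: int = 2,
    noise_sd: float = 0.5,
    group_effect: float = 1.0,
    off_support_sd: float = 0.02,
    seed: int = 0,
):
    """Generate (ExpressionMatrix, SignatureAtlas, labels, SyntheticTruth).

    Signatures are random gene sets (moderate overlap allowed).  The first
    ``n_active`` signatures each drive one latent factor: loading 1 on the
    signature's genes, small non-negative off-support noise elsewhere.
    Sample scores are standard normal; the first ``n_differential`` active
    factors are shifted by ``group_effect`` in group 1.  The expression
    matrix is Z·B plus N(0, noise_sd²) noise on the log scale, shifted so
    the minimum is ≥ −1 (the log image of a zero TPM), with balanced
    binary group labels.
    """
    if n_active > n_signatures:
        raise ValueError("n_active cannot exceed n_signatures")
    if signature_size > n_genes:
        raise ValueError("signature_size cannot exceed n_genes")
    n_differential = min(n_differential, n_active)

    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]

    signatures = []
    supports = []
    for s in range(n_signatures):
        idx = rng.choice(n_genes, size=signature_size, replace=False)
        supports.append(np.sort(idx))
        if s < n_active:
            meta = {"cell_type": _ACTIVE_CELL_TYPES[s % len(_ACTIVE_CELL_TYPES)],
                    "author": "synthetic", "species": "synthetic",
                    "clinical_condition": "synthetic"}
        else:
            meta = {"author": "synthetic", "species": "synthetic",
                    "clinical_condition": "synthetic"}
        signatures.append(
            Signature(f"sig{s + 1:03d}", tuple(genes[i] for i in supports[s]), meta)
        )
    atlas = SignatureAtlas(signatures)

    Z = np.abs(rng.normal(0.0, off_support_sd, size=(n_genes, n_active)))
    for k in range(n_active):
        Z[supports[k], k] = 1.0

    labels = pd.Series(
        np.array([0] * (n_samples // 2) + [1] * (n_samples - n_samples // 2)),
        index=samples, name="group",
    )
    B = rng.normal(size=(n_active, n_samples))
    differential = [(k, float(group_effect)) for k in range(n_differential)]
    for k, effect in differential:
        B[k, labels.to_numpy() == 1] += effect

    Y = Z @ B + rng.normal(0.0, noise_sd, size=(n_genes, n_samples)) if noise_sd > 0 else Z @ B
    shift = -1.0 - Y.min()
    if shift > 0:
        Y = Y + shift

    em = ExpressionMatrix(genes, samples, Y, LOG2_TPM_HALF)
    truth = SyntheticTruth(
        Z_true=Z,
        B_true=B,
        active_signatures=[(f"sig{k + 1:03d}", k) for k in range(n_active)],
        differential_lvs=differential,
        noise_sd=noise_sd,
        seed=seed,
    )
    return em, atlas, labels, truth
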