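"""Prior-knowledge-constrained penalized matrix decomposition.

A genes × samples expression matrix Y is factored as Y ≈ ZB, with the
gene loadings Z encouraged to align with a binary prior-knowledge matrix C
through Z ≈ CU.  The fit minimizes

    ‖Y − ZB‖²_F + λ1‖Z − CU‖²_F + λ2‖B‖²_F + λ3·Σ|U|

by block coordinate descent: a closed-form ridge update for B, exact
cyclic coordinate descent with non-negativity for Z, and coordinate
descent with soft-thresholding (clipped at zero) for U.  Each block update
is an exact minimizer over its block, so the outer-iteration loss trace is
non-increasing.

The number of latent variables can be chosen by a permutation test on the
singular-value scree (``estimate_num_lvs``).  A fitted model projects new
datasets onto the frozen loadings via the same ridge formula used for B.

The canonical entry point is the sklearn-style :class:`PlierDecomposition`
estimator (samples × features orientation); the module-level ``fit_plier``
/ ``transform_plier`` functions wrap it for the genes × samples domain
types and add directory serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import (
    LOG2_TPM_HALF,
    DataError,
    ExpressionMatrix,
    PriorMatrix,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# numerics


def plier_loss(Y, Z, B, C, U, lambda1, lambda2, lambda3) -> float:
    """Penalized reconstruction loss
    ``‖Y−ZB‖² + λ1‖Z−CU‖² + λ2‖B‖² + λ3·Σ|U|`` (Frobenius norms squared)."""
    Y, Z, B, C, U = (np.asarray(a, dtype=float) for a in (Y, Z, B, C, U))
    if Y.shape != (Z.shape[0], B.shape[1]) or Z.shape[1] != B.shape[0]:
        raise ValueError("Y, Z, B dimensions are not conformable")
    if C.shape != (Z.shape[0], U.shape[0]) or U.shape[1] != Z.shape[1]:
        raise ValueError("C, U, Z dimensions are not conformable")
    value = (
        np.linalg.norm(Y - Z @ B) ** 2
        + lambda1 * np.linalg.norm(Z - C @ U) ** 2
        + lambda2 * np.linalg.norm(B) ** 2
        + lambda3 * np.abs(U).sum()
    )
    if not np.isfinite(value):
        raise ValueError("non-finite loss")
    return float(value)


def _standardize_rows(Y: np.ndarray, means=None, sds=None):
    """Z-score each gene row; zero-variance rows get sd 1 (standardize to 0)."""
    if means is None:
        means = Y.mean(axis=1)
        sds = Y.std(axis=1)
        sds = np.where(sds <= 0, 1.0, sds)
    return (Y - means[:, None]) / sds[:, None], means, sds


def _cd_quadratic(X, G, P, l1=0.0, nonneg=True, sweeps=10, tol=1e-10):
    """Cyclic coordinate descent on  Σ_t  x_tᵀGx_t − 2p_tᵀx_t + l1·Σ|x|,
    columns x_t = X[:, t] independent, coupling G shared.  Exact coordinate
    minimization, hence monotone in the objective.  X is updated in place."""
    diag = np.diag(G)
    scale = max(np.abs(X).max(initial=0.0), np.abs(P).max(initial=0.0), 1.0)
    for _ in range(sweeps):
        max_delta = 0.0
        for d in range(X.shape[0]):
            gd = diag[d]
            if gd <= _EPS:
                X[d, :] = 0.0
                continue
            c = (P[d] - G[d] @ X + gd * X[d]) / gd
            t = l1 / (2.0 * gd)
            if nonneg:
                new = np.maximum(c - t, 0.0)
            else:
                new = np.sign(c) * np.maximum(np.abs(c) - t, 0.0)
            max_delta = max(max_delta, float(np.abs(new - X[d]).max(initial=0.0)))
            X[d] = new
        if max_delta < tol * scale:
            break
    return X


def _ridge_scores(Z: np.ndarray, Y: np.ndarray, lambda2: float) -> np.ndarray:
    """Closed-form ridge solve  B = (ZᵀZ + λ2 I)⁻¹ ZᵀY."""
    K = Z.shape[1]
    gram = Z.T @ Z + lambda2 * np.eye(K)
    try:
        return np.linalg.solve(gram, Z.T @ Y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(gram, Z.T @ Y, rcond=None)[0]


def estimate_num_lvs(Y, n_perm: int = 20, quantile: float = 0.95, seed: int = 0) -> int:
    """Permutation estimate of the number of informative components.

    Singular values of the row-standardized matrix are compared with the
    per-component ``quantile`` of singular values obtained after permuting
    the entries independently within each row; the estimate is the number
    of leading components whose observed singular value exceeds its
    permutation threshold.
    """
    if isinstance(Y, ExpressionMatrix):
        Y = Y.values
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or min(Y.shape) < 2:
        raise ValueError("need a 2-d matrix with at least 2 rows and columns")
    if np.ptp(Y) == 0:
        raise ValueError("constant matrix has no estimable rank structure")
    Ystd, _, _ = _standardize_rows(Y)
    s_obs = np.linalg.svd(Ystd, compute_uv=False)
    rng = np.random.default_rng(seed)
    s_perm = np.empty((n_perm, len(s_obs)))
    for p in range(n_perm):
        s_perm[p] = np.linalg.svd(rng.permuted(Ystd, axis=1), compute_uv=False)
    thresholds = np.quantile(s_perm, quantile, axis=0)
    above = s_obs > thresholds
    k = 0
    while k < len(above) and above[k]:
        k += 1
    return k


# ---------------------------------------------------------------------------
# estimator


class PlierDecomposition(TransformerMixin, BaseEstimator):
    """Prior-knowledge-guided decomposition as an sklearn transformer.

    Parameters
    ----------
    prior : PriorMatrix or DataFrame (genes × signatures)
        Binary gene-set membership matrix C anchoring latent variables.
    n_components : int or "auto"
        Number of latent variables k; "auto" runs the permutation scree test.
    frac : float in (0, 1]
        Sparsity control for the signature-weight matrix U: the automatic λ3
        is calibrated so that roughly this fraction of the unpenalized
        positive U candidates survives soft-thresholding at initialization.
        Smaller values give a sparser U (0.5 by default).
    lambda1, lambda2, lambda3 : float or None
        Penalty weights; None triggers automatic calibration (λ1 = λ2 = the
        residual-variance estimate of the standardized scree beyond rank k,
        λ3 from `frac`).
    standardize : bool
        Z-score genes before fitting (training means/SDs are stored and
        reused at transform time).
    nonneg : bool
        Enforce Z ≥ 0 and U ≥ 0 elementwise.
    random_state : int
        Seed for the permutation scree; the fit itself is deterministic.

    Attributes
    ----------
    loadings_ : ndarray (n_genes, k)         -- Z
    scores_ : ndarray (k, n_samples)         -- B for the training data
    signature_weights_ : ndarray (S, k)      -- U
    loss_trace_ : ndarray                    -- per-outer-iteration loss
    gene_means_, gene_sds_ : ndarray         -- training standardization
    lv_names_ : list of str
    """

    def __init__(
        self,
        prior=None,
        n_components="auto",
        frac=0.5,
        lambda1=None,
        lambda2=None,
        lambda3=None,
        standardize=True,
        nonneg=True,
        max_outer_iter=200,
        tol=1e-6,
        inner_sweeps=10,
        n_perm=20,
        quantile=0.95,
        min_overlap_warn=0.8,
        min_overlap_error=0.5,
        random_state=0,
    ):
        self.prior = prior
        self.n_components = n_components
        self.frac = frac
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.standardize = standardize
        self.nonneg = nonneg
        self.max_outer_iter = max_outer_iter
        self.tol = tol
        self.inner_sweeps = inner_sweeps
        self.n_perm = n_perm
        self.quantile = quantile
        self.min_overlap_warn = min_overlap_warn
        self.min_overlap_error = min_overlap_error
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _prior_frame(self) -> pd.DataFrame:
        if self.prior is None:
            raise ValueError("a prior matrix is required")
        if isinstance(self.prior, PriorMatrix):
            return self.prior.to_frame()
        return pd.DataFrame(self.prior)

    def _coerce_X(self, X):
        """X is samples × genes; returns (values, sample_ids, gene_ids)."""
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.index), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, list(range(X.shape[0])), None

    def _svd_init(self, Ystd: np.ndarray, k: int) -> np.ndarray:
        Usvd, s, _ = np.linalg.svd(Ystd, full_matrices=False)
        Z0 = Usvd[:, :k] * s[:k]
        # orient each column positively, then project onto the constraint set
        flip = (Z0 < 0).sum(axis=0) > (Z0 > 0).sum(axis=0)
        Z0[:, flip] *= -1.0
        if self.nonneg:
            Z0 = np.maximum(Z0, 0.0)
            dead = Z0.max(axis=0) <= 0
            if dead.any():
                Z0[:, dead] = np.abs(Usvd[:, :k][:, dead] * s[:k][dead])
        return Z0

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the decomposition.  X is samples × genes (log-scale expression);
        gene columns must match the prior matrix rows (by name for DataFrames,
        by position for arrays)."""
        Cdf = self._prior_frame()
        values, sample_ids, gene_ids = self._coerce_X(X)
        if gene_ids is not None:
            missing = [g for g in gene_ids if g not in Cdf.index]
            if missing:
                raise ValueError(
                    f"{len(missing)} expression genes absent from the prior matrix "
                    f"(e.g. {missing[:3]}); filter genes first"
                )
            Cdf = Cdf.reindex(gene_ids)
        elif values.shape[1] != Cdf.shape[0]:
            raise ValueError("n_features does not match the prior matrix rows")
        keep = Cdf.to_numpy().sum(axis=0) >= 1
        if not keep.all():
            logger.warning("dropping %d empty prior columns", int((~keep).sum()))
            Cdf = Cdf.loc[:, keep]
        C = Cdf.to_numpy(dtype=float)

        Y = values.T  # genes × samples internally
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite expression values")
        n_genes, n_samples = Y.shape

        if self.standardize:
            Ystd, means, sds = _standardize_rows(Y)
        else:
            Ystd = Y.copy()
            means = np.zeros(n_genes)
            sds = np.ones(n_genes)

        if self.n_components == "auto":
            k = max(
                estimate_num_lvs(
                    Ystd, n_perm=self.n_perm, quantile=self.quantile, seed=self.random_state
                ),
                1,
            )
            k = min(k, min(n_genes, n_samples))
            logger.info("permutation scree selected k=%d", k)
        else:
            k = int(self.n_components)
        if not 1 <= k <= min(n_genes, n_samples):
            raise ValueError(f"k={k} must be in [1, min(n_genes, n_samples)]")

        sv = np.linalg.svd(Ystd, compute_uv=False)
        if self.lambda1 is None or self.lambda2 is None:
            # residual variance of the scree beyond rank k, per degree of freedom
            resid = float(np.sum(sv[k:] ** 2))
            dof = max((n_genes - k) * (n_samples - k), 1)
            sigma2 = max(resid / dof, 1e-8)
        lam1 = float(self.lambda1) if self.lambda1 is not None else sigma2
        lam2 = float(self.lambda2) if self.lambda2 is not None else sigma2

        Z = self._svd_init(Ystd, k)
        S = C.shape[1]
        U = np.zeros((S, k))
        Hu = lam1 * (C.T @ C)

        if self.lambda3 is not None:
            lam3 = float(self.lambda3)
        elif lam1 <= 0:
            lam3 = 0.0
        else:
            # unpenalized candidate U at initialization sets the threshold scale
            U0 = _cd_quadratic(
                np.zeros((S, k)), Hu, lam1 * (C.T @ Z), l1=0.0,
                nonneg=self.nonneg, sweeps=30,
            )
            pos = np.abs(U0[np.abs(U0) > 0])
            if pos.size == 0:
                lam3 = 0.0
            else:
                tau = float(np.quantile(pos, 1.0 - self.frac))
                lam3 = 2.0 * lam1 * tau * float(np.median((C * C).sum(axis=0)))

        B = _ridge_scores(Z, Ystd, lam2)
        loss_trace = [plier_loss(Ystd, Z, B, C, U, lam1, lam2, lam3)]
        for _ in range(self.max_outer_iter):
            B = _ridge_scores(Z, Ystd, lam2)
            G = B @ B.T + lam1 * np.eye(k)
            P = Ystd @ B.T + lam1 * (C @ U)
            Z = _cd_quadratic(
                Z.T, G, P.T, l1=0.0, nonneg=self.nonneg,
                sweeps=self.inner_sweeps, tol=0.01 * self.tol,
            ).T
            if lam1 > 0:
                U = _cd_quadratic(
                    U, Hu, lam1 * (C.T @ Z), l1=lam3, nonneg=self.nonneg,
                    sweeps=self.inner_sweeps, tol=0.01 * self.tol,
                )
            loss = plier_loss(Ystd, Z, B, C, U, lam1, lam2, lam3)
            prev = loss_trace[-1]
            loss_trace.append(loss)
            if abs(prev - loss) < self.tol * max(abs(prev), _EPS):
                break
        B = _ridge_scores(Z, Ystd, lam2)  # consistent with the frozen final Z
        loss_trace.append(plier_loss(Ystd, Z, B, C, U, lam1, lam2, lam3))

        width = max(3, len(str(k)))
        self.lv_names_ = [f"LV{i + 1:0{width}d}" for i in range(k)]
        self.n_components_ = k
        self.loadings_ = Z
        self.scores_ = B
        self.signature_weights_ = U
        self.lambda1_, self.lambda2_, self.lambda3_ = lam1, lam2, lam3
        self.loss_trace_ = np.asarray(loss_trace)
        self.gene_means_ = means
        self.gene_sds_ = sds
        self.gene_universe_ = list(gene_ids) if gene_ids is not None else list(range(n_genes))
        self.signature_names_ = list(Cdf.columns)
        self.prior_matrix_ = C
        self.sample_ids_ = sample_ids
        self.n_features_in_ = n_genes
        if gene_ids is not None:
            self.feature_names_in_ = np.asarray(gene_ids, dtype=object)
        return self

    def _align_new(self, X):
        """Align a new samples × genes matrix to the training gene universe,
        standardize with training stats, zero-fill missing genes."""
        values, sample_ids, gene_ids = self._coerce_X(X)
        universe = self.gene_universe_
        if gene_ids is None:
            if values.shape[1] != len(universe):
                raise ValueError("array input must match the training gene count")
            aligned = values.T
            present = np.ones(len(universe), dtype=bool)
        else:
            pos = {g: i for i, g in enumerate(gene_ids)}
            idx = np.array([pos.get(g, -1) for g in universe])
            present = idx >= 0
            aligned = np.zeros((len(universe), values.shape[0]))
            aligned[present] = values.T[idx[present]]
        overlap = present.mean()
        if overlap < self.min_overlap_error:
            raise ValueError(
                f"only {overlap:.0%} of model genes present in the new dataset"
            )
        if overlap < self.min_overlap_warn:
            logger.warning("gene overlap with the model is %.0f%%", 100 * overlap)
        # with standardize=False the stored stats are (0, 1) and this is a no-op
        Xstd = (aligned - self.gene_means_[:, None]) / self.gene_sds_[:, None]
        Xstd[~present] = 0.0  # missing genes sit at the training mean
        return Xstd, sample_ids

    def transform(self, X):
        """Project new samples onto the frozen loadings:
        B′ = (ZᵀZ + λ2 I)⁻¹ ZᵀY′.  Returns samples × LVs."""
        check_is_fitted(self, "loadings_")
        Ynew, _ = self._align_new(X)
        return _ridge_scores(self.loadings_, Ynew, self.lambda2_).T

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "lv_names_")
        return np.asarray(self.lv_names_, dtype=object)


# ---------------------------------------------------------------------------
# domain-facing wrappers and serialization


@dataclass
class LVScores:
    """K × M′ latent-variable score matrix row-aligned to a trained model."""

    lv_names: list
    samples: list
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lv_names, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LVScores":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class PlierModel:
    """A fitted decomposition in genes × samples convention, serializable to
    a directory of TSV/YAML files (round-trip value-exact)."""

    Z: pd.DataFrame  # genes × LVs
    B: pd.DataFrame  # LVs × samples
    U: pd.DataFrame  # signatures × LVs
    config: dict
    gene_stats: pd.DataFrame  # genes × (mean, sd)
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def lv_names(self) -> list:
        return list(self.Z.columns)

    @property
    def gene_universe(self) -> list:
        return list(self.Z.index)

    @property
    def signature_names(self) -> list:
        return list(self.U.index)

    @classmethod
    def from_estimator(cls, est: PlierDecomposition) -> "PlierModel":
        check_is_fitted(est, "loadings_")
        config = est.get_params(deep=False)
        config.pop("prior")
        config.update(
            n_components=est.n_components_,
            lambda1=est.lambda1_,
            lambda2=est.lambda2_,
            lambda3=est.lambda3_,
        )
        return cls(
            Z=pd.DataFrame(est.loadings_, index=est.gene_universe_, columns=est.lv_names_),
            B=pd.DataFrame(est.scores_, index=est.lv_names_, columns=est.sample_ids_),
            U=pd.DataFrame(
                est.signature_weights_, index=est.signature_names_, columns=est.lv_names_
            ),
            config=config,
            gene_stats=pd.DataFrame(
                {"mean": est.gene_means_, "sd": est.gene_sds_}, index=est.gene_universe_
            ),
            loss_trace=est.loss_trace_,
        )

    def to_estimator(self, prior: PriorMatrix | None = None) -> PlierDecomposition:
        """Rehydrate an estimator able to transform new data."""
        est = PlierDecomposition(prior=prior, **{
            k: v for k, v in self.config.items()
            if k in PlierDecomposition().get_params()
        })
        est.loadings_ = self.Z.to_numpy()
        est.scores_ = self.B.to_numpy()
        est.signature_weights_ = self.U.to_numpy()
        est.lambda1_ = float(self.config["lambda1"])
        est.lambda2_ = float(self.config["lambda2"])
        est.lambda3_ = float(self.config["lambda3"])
        est.gene_means_ = self.gene_stats["mean"].to_numpy()
        est.gene_sds_ = self.gene_stats["sd"].to_numpy()
        est.gene_universe_ = self.gene_universe
        est.signature_names_ = self.signature_names
        est.lv_names_ = self.lv_names
        est.sample_ids_ = list(self.B.columns)
        est.n_components_ = len(self.lv_names)
        est.loss_trace_ = self.loss_trace
        return est

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (("Z", self.Z), ("B", self.B), ("U", self.U),
                         ("gene_stats", self.gene_stats)):
            df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.17g")
        pd.DataFrame({"loss": self.loss_trace}).to_csv(
            outdir / "loss_trace.tsv", sep="\t", index=False, float_format="%.17g"
        )
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)

    @classmethod
    def load(cls, outdir) -> "PlierModel":
        outdir = Path(outdir)
        read = lambda n: pd.read_csv(
            outdir / f"{n}.tsv", sep="\t", index_col=0, float_precision="round_trip"
        ).astype(float)
        with open(outdir / "config.yaml") as fh:
            config = yaml.safe_load(fh)
        loss = pd.read_csv(
            outdir / "loss_trace.tsv", sep="\t", float_precision="round_trip"
        )["loss"].to_numpy()
        return cls(read("Z"), read("B"), read("U"), config, read("gene_stats"), loss)


def fit_plier(Y: ExpressionMatrix, C: PriorMatrix, **config) -> PlierModel:
    """Fit the decomposition on a log-scale genes × samples expression matrix."""
    if Y.scale != LOG2_TPM_HALF:
        raise DataError("fit expects a log2(TPM+0.5) matrix; run log_transform first")
    est = PlierDecomposition(prior=C, **config)
    est.fit(Y.to_frame().T)
    return PlierModel.from_estimator(est)


def transform_plier(model: PlierModel, Ynew: ExpressionMatrix) -> LVScores:
    """Project a new preprocessed dataset onto a trained model's loadings."""
    if Ynew.scale != LOG2_TPM_HALF:
        raise DataError("transform expects a log2(TPM+0.5) matrix")
    est = model.to_estimator()
    values = est.transform(Ynew.to_frame().T).T
    return LVScores(model.lv_names, list(Ynew.samples), values)
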