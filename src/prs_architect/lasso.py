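"""L1-penalized sparse linear prediction by cyclic coordinate descent.

The model is the plain additive one, ``y = X beta + eps`` with genotype
columns ``x in {0,1,2}``, fitted by minimizing

    O_lambda(beta) = 1/2 ||y - X beta||^2 + n * lambda * ||beta||_1,

whose coordinate-wise minimizer is an exact soft-threshold update. The
penalty drives most weights to zero, leaving a sparse active set; it also
disfavors keeping several mutually correlated SNPs, which is why the
variance arithmetic elsewhere in the package can treat active SNPs as
largely uncorrelated.

Shape follows statsmodels: build a :class:`SparseLinearModel` from data,
call ``fit`` / ``fit_path`` / ``fit_cv``, get :class:`SparseLinearResults`
carrying estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Predictor, PredictorSNP

__all__ = [
    "SparseLinearModel",
    "SparseLinearResults",
    "pairwise_snp_correlation",
]


def _soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


class SparseLinearModel:
    """L1-penalized linear model of a phenotype on genotype columns.

    Parameters
    ----------
    genotypes : (n, p) array
        Minor-allele counts (or any numeric design); columns are centered
        and, by default, scaled to unit variance before fitting. Fitted
        weights are always reported back on the original per-allele scale.
    phenotype : (n,) array
        Continuous trait or 0/1 case-control labels; centered internally.
        Case-control labels are fitted with the same squared-error
        objective (linear probability), not logistic loss.
    snp_ids : optional sequence of column names.
    standardize : scale columns to unit variance (default True).
    """

    def __init__(self, genotypes, phenotype, snp_ids=None, standardize=True):
        X = np.asarray(genotypes, dtype=float)
        y = np.asarray(phenotype, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValidationError(
                f"genotypes must be (n, p) and phenotype (n,); got {X.shape}, {y.shape}"
            )
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValidationError("need n >= 1 individuals and p >= 1 SNPs")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("genotypes and phenotype must be finite")
        self.n, self.p = X.shape
        self.snp_ids = (
            list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(self.p)]
        )
        if len(self.snp_ids) != self.p:
            raise ValidationError("snp_ids length must match the number of columns")
        self._y_mean = y.mean()
        self._yc = y - self._y_mean
        self._col_mean = X.mean(axis=0)
        Z = X - self._col_mean
        if standardize:
            sd = Z.std(axis=0, ddof=0)
            sd[sd == 0.0] = 1.0  # constant columns stay zero after centering
        else:
            sd = np.ones(self.p)
        self._col_sd = sd
        self._Z = Z / sd
        self._col_sq = np.einsum("ij,ij->j", self._Z, self._Z)
        self.standardize = standardize

    # -- penalty grid -------------------------------------------------------

    def lambda_max(self) -> float:
        """Smallest penalty at which the fitted model is exactly empty."""
        return float(np.max(np.abs(self._Z.T @ self._yc)) / self.n)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        lam: float,
        tol: float = 1e-6,
        max_sweeps: int = 1000,
        start: np.ndarray | None = None,
    ) -> "SparseLinearResults":
        """Minimize the objective at one penalty by cyclic coordinate descent.

        Sweeps cycle over coordinates with exact soft-threshold updates and
        stop when the largest standardized-weight change in a sweep falls
        below ``tol``. ``start`` warm-starts from a previous solution
        (standardized scale).
        """
        if lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {lam}")
        Z, y, n, p = self._Z, self._yc, self.n, self.p
        beta = np.zeros(p) if start is None else np.array(start, dtype=float)
        r = y - Z @ beta if start is not None else y.copy()
        nl = n * lam

        def kkt_residual(resid, b):
            grad = Z.T @ resid
            active = np.flatnonzero(b)
            viol = np.maximum(np.abs(grad) - nl, 0.0)
            viol[active] = np.abs(grad[active] - nl * np.sign(b[active]))
            return float(np.max(viol)) if p else 0.0

        trace: list[float] = []
        converged = False
        sweeps = 0
        kkt = np.inf
        for sweeps in range(1, max_sweeps + 1):
            max_delta = 0.0
            for j in range(p):
                cj = self._col_sq[j]
                if cj == 0.0:
                    continue
                bj = beta[j]
                rho = Z[:, j] @ r + cj * bj
                bnew = _soft_threshold(rho, nl) / cj
                if bnew != bj:
                    r += Z[:, j] * (bj - bnew)
                    beta[j] = bnew
                    max_delta = max(max_delta, abs(bnew - bj))
            trace.append(0.5 * float(r @ r) + nl * float(np.abs(beta).sum()))
            # stop only once both the weights and the stationarity
            # conditions have settled
            if max_delta < tol:
                kkt = kkt_residual(r, beta)
                if kkt <= 10.0 * tol:
                    converged = True
                    break
        if not np.isfinite(kkt) or not converged:
            kkt = kkt_residual(r, beta)
        return SparseLinearResults(
            model=self,
            lam=float(lam),
            tol=tol,
            params_std=beta,
            objective_trace=np.array(trace),
            n_sweeps=sweeps,
            converged=converged,
            kkt_residual=kkt,
        )

    def fit_path(
        self,
        n_lambdas: int = 50,
        ratio: float = 1e-3,
        tol: float = 1e-6,
        max_sweeps: int = 1000,
    ) -> list["SparseLinearResults"]:
        """Warm-started fits along a geometric penalty grid.

        The grid runs from ``lambda_max`` (empty model) down to
        ``ratio * lambda_max``. Active-set size typically grows as the
        penalty shrinks, but strict monotonicity is not guaranteed by the
        LASSO and is not enforced.
        """
        if n_lambdas < 2:
            raise ValidationError("n_lambdas must be >= 2")
        if not (0.0 < ratio < 1.0):
            raise ValidationError(f"ratio must lie in (0, 1), got {ratio}")
        lmax = self.lambda_max()
        grid = lmax * ratio ** (np.arange(n_lambdas) / (n_lambdas - 1))
        # guard the top of the path against ulp-level differences between
        # the lambda_max reduction and the per-coordinate dot products
        grid[0] = lmax * (1.0 + 1e-10)
        fits: list[SparseLinearResults] = []
        start = None
        for lam in grid:
            res = self.fit(lam, tol=tol, max_sweeps=max_sweeps, start=start)
            start = res.params_std.copy()
            fits.append(res)
        return fits

    def fit_cv(
        self,
        n_lambdas: int = 50,
        ratio: float = 1e-3,
        val_fraction: float = 0.2,
        seed: int = 0,
        tol: float = 1e-6,
        max_sweeps: int = 1000,
        parsimony_tol: float = 0.01,
    ) -> "SparseLinearResults":
        """Select the penalty on a held-out split, then refit on all data.

        A seeded ``val_fraction`` split is held out; the path is fitted on
        the training part and each fit scored by the Pearson correlation of
        its predictions with the held-out phenotype. The selected penalty is
        the *largest* (sparsest) one whose validation correlation is within
        ``parsimony_tol`` (relative) of the best — the usual parsimony rule
        for LASSO paths. The returned results carry the full selection table
        in ``cv_table``.
        """
        if not (0.0 < val_fraction < 1.0):
            raise ValidationError("val_fraction must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n)
        n_val = max(1, int(round(val_fraction * self.n)))
        val, train = perm[:n_val], perm[n_val:]
        if train.size < 2:
            raise ValidationError("too few samples left for training")
        Xt = self._Z[train] * self._col_sd + self._col_mean
        Xv = self._Z[val] * self._col_sd + self._col_mean
        yt = self._yc[train] + self._y_mean
        yv = self._yc[val] + self._y_mean
        sub = SparseLinearModel(
            Xt, yt, snp_ids=self.snp_ids, standardize=self.standardize
        )
        path = sub.fit_path(
            n_lambdas=n_lambdas, ratio=ratio, tol=tol, max_sweeps=max_sweeps
        )
        rows = []
        for res in path:
            pred = Xv @ res.params
            if np.std(pred) == 0.0 or np.std(yv) == 0.0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(pred, yv)[0, 1])
            rows.append(
                {
                    "lambda": res.lam,
                    "active_size": res.active_set.size,
                    "val_correlation": corr,
                }
            )
        cv_table = pd.DataFrame(rows)
        best = cv_table["val_correlation"].max()
        ok = cv_table["val_correlation"] >= best - parsimony_tol * abs(best)
        lam_star = float(cv_table.loc[ok, "lambda"].max())
        final = self.fit(lam_star, tol=tol, max_sweeps=max_sweeps)
        final.cv_table = cv_table
        return final


@dataclass
class SparseLinearResults:
    """A fitted sparse linear predictor at one penalty.

    ``params`` are per-allele effect sizes on the original genotype scale
    (standardization undone); ``params_std`` the internal standardized
    weights. ``objective_trace`` is the objective after each sweep and is
    non-increasing; ``kkt_residual`` is the largest violation of the
    stationarity conditions at the solution.
    """

    model: SparseLinearModel
    lam: float
    tol: float
    params_std: np.ndarray
    objective_trace: np.ndarray
    n_sweeps: int
    converged: bool
    kkt_residual: float
    cv_table: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def params(self) -> np.ndarray:
        return self.params_std / self.model._col_sd

    @property
    def active_set(self) -> np.ndarray:
        """Indices of SNPs with nonzero fitted weight."""
        return np.flatnonzero(self.params_std)

    @property
    def active_snp_ids(self) -> list[str]:
        return [self.model.snp_ids[j] for j in self.active_set]

    def predict(self, genotypes) -> np.ndarray:
        X = np.asarray(genotypes, dtype=float)
        return self.model._y_mean + (X - self.model._col_mean) @ self.params

    def to_predictor(self, manifest: Predictor, phenotype: str | None = None) -> Predictor:
        """Emit the active set as a :class:`Predictor` using manifest metadata.

        The manifest supplies coordinates and MAF for every model column (by
        SNP id); the emitted predictor carries the fitted per-allele betas
        and is ready for the variance/genic/exome/overlap analyses.
        """
        if self.active_set.size == 0:
            raise ValidationError(
                "active set is empty; lower lambda (e.g. refit deeper on the path)"
            )
        meta = {s.snp_id: s for s in manifest.snps}
        missing = [sid for sid in self.active_snp_ids if sid not in meta]
        if missing:
            raise ValidationError(f"manifest lacks SNP(s) {missing[:5]!r}...")
        params = self.params
        snps = []
        for j in self.active_set:
            m = meta[self.model.snp_ids[j]]
            snps.append(
                PredictorSNP(
                    snp_id=m.snp_id,
                    chromosome=m.chromosome,
                    position=m.position,
                    beta=float(params[j]),
                    maf=m.maf,
                    counted_allele=m.counted_allele,
                )
            )
        return Predictor(phenotype or f"{manifest.phenotype}_fit", snps)

    def summary(self) -> str:
        lines = [
            "Sparse linear model (L1, cyclic coordinate descent)",
            "=" * 53,
            f"n obs:            {self.model.n}",
            f"p SNPs:           {self.model.p}",
            f"lambda:           {self.lam:.6g}",
            f"active set size:  {self.active_set.size}",
            f"sweeps:           {self.n_sweeps} ({'converged' if self.converged else 'max sweeps reached'})",
            f"final objective:  {self.objective_trace[-1]:.6g}",
            f"max KKT residual: {self.kkt_residual:.3g}",
        ]
        if self.cv_table is not None:
            best = self.cv_table.loc[self.cv_table["val_correlation"].idxmax()]
            lines.append(
                f"validation:       best r={best['val_correlation']:.4f} "
                f"at lambda={best['lambda']:.6g}"
            )
        return "\n".join(lines)


def pairwise_snp_correlation(genotypes, index_pairs) -> np.ndarray:
    """Sample Pearson correlation of genotype column pairs.

    Diagnostic behind treating active SNPs as uncorrelated in the variance
    arithmetic. ``index_pairs`` is an iterable of (j, k) column indices.
    Zero-variance columns have no defined correlation and raise.
    """
    X = np.asarray(genotypes, dtype=float)
    out = []
    for j, k in index_pairs:
        a, b = X[:, j], X[:, k]
        if a.std() == 0.0 or b.std() == 0.0:
            raise ValidationError(
                f"correlation undefined: column {j if a.std() == 0 else k} has zero variance"
            )
        out.append(float(np.corrcoef(a, b)[0, 1]))
    return np.array(out)
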