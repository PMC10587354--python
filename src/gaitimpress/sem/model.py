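"""Maximum-likelihood covariance-structure estimation.

:class:`SemModel` is built from data (or directly from a sample covariance
matrix) and a :class:`~gaitimpress.sem.spec.SemSpec`; ``fit()`` minimizes
the ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

by seeded multi-start quasi-Newton optimization and returns a
:class:`SemResults` carrying estimates, the standardized solution, and the
chi-square / GFI / AGFI / CFI / RMSEA fit indices (chi-square uses the
(N-1) multiplier).  Non-convergence is a reportable outcome (``converged``
flag), not an exception: badly specified models are expected to fail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .spec import SemSpec

_PENALTY = 1e10


def _fml(spec: SemSpec, theta: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    p = S.shape[0]
    try:
        sigma = spec.implied_covariance(theta)
    except ValueError:
        return _PENALTY
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY + float(np.sum(theta**2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    x = np.linalg.solve(L, S)
    inv_term = float(np.trace(np.linalg.solve(L.T, x)))
    f = logdet + inv_term - logdet_S - p
    if not np.isfinite(f):
        return _PENALTY
    return f


class SemModel:
    """Covariance-structure model bound to one sample.

    Parameters
    ----------
    spec : SemSpec
    S : (p, p) array
        Sample covariance of the observed variables, in the order of
        ``spec.observed``.
    nobs : int
        Number of observation rows behind S.
    """

    def __init__(self, spec: SemSpec, S: np.ndarray, nobs: int):
        S = np.asarray(S, dtype=float)
        p = len(spec.observed)
        if S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p} for this spec")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("S must be positive-definite") from exc
        if nobs <= p:
            raise ValueError("nobs must exceed the number of observed variables")
        if spec.df < 0:
            raise ValueError(
                f"unidentified spec: {spec.n_free} free parameters, df = {spec.df} < 0"
            )
        self.spec = spec
        self.S = S
        self.nobs = int(nobs)
        sign, logdet = np.linalg.slogdet(S)
        self._logdet_S = float(logdet)

    @classmethod
    def from_dataframe(cls, spec: SemSpec, data: pd.DataFrame) -> "SemModel":
        """Build from raw observation rows (columns must cover spec.observed)."""
        missing = [v for v in spec.observed if v not in data.columns]
        if missing:
            raise ValueError(f"data lacks observed variables: {missing}")
        sub = data[spec.observed].dropna()
        S = np.cov(sub.to_numpy(dtype=float), rowvar=False, ddof=1)
        return cls(spec, S, nobs=len(sub))

    # -- starting values -----------------------------------------------------

    def _start(self) -> np.ndarray:
        diag = np.diag(self.S)
        idx = {v: i for i, v in enumerate(self.spec.observed)}
        first_ind = {}
        for p_ in self.spec.loadings:
            first_ind.setdefault(p_.lhs, p_.rhs)
        theta = []
        for p_ in self.spec.free_parameters:
            if p_.value is not None:
                theta.append(p_.value)
            elif p_.kind == "loading":
                theta.append(0.7)
            elif p_.kind == "path":
                theta.append(0.1)
            elif p_.kind == "cov":
                theta.append(0.05)
            else:  # variance
                v = p_.lhs
                if v in idx:
                    theta.append(0.5 * diag[idx[v]])
                else:
                    anchor = first_ind.get(v)
                    theta.append(0.5 * diag[idx[anchor]] if anchor in idx else 0.5)
        return np.asarray(theta, dtype=float)

    def _bounds(self):
        b = []
        for p_ in self.spec.free_parameters:
            if p_.kind == "var":
                b.append((1e-8, None))
            else:
                b.append((None, None))
        return b

    # -- estimation ----------------------------------------------------------

    def fit(
        self,
        n_starts: int = 10,
        seed: int = 0,
        gtol: float = 1e-9,
        maxiter: int = 2000,
    ) -> "SemResults":
        """Multi-start L-BFGS-B minimization of the ML discrepancy."""
        rng = np.random.default_rng(seed)
        base = self._start()
        bounds = self._bounds()
        obj = lambda th: _fml(self.spec, th, self.S, self._logdet_S)

        best = None
        for k in range(max(1, n_starts)):
            x0 = base if k == 0 else base + rng.normal(0.0, 0.3, base.shape) * (
                1.0 + np.abs(base)
            )
            x0 = np.array(
                [max(x, 1e-6) if b[0] is not None else x for x, b in zip(x0, bounds)]
            )
            res = minimize(
                obj,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res

        theta = np.asarray(best.x, dtype=float)
        fmin = float(best.fun)
        grad_ok = bool(np.max(np.abs(best.jac)) < 1e-4 * max(1.0, abs(fmin) + 1.0))
        pd_ok = True
        try:
            np.linalg.cholesky(self.spec.implied_covariance(theta))
        except (np.linalg.LinAlgError, ValueError):
            pd_ok = False
        converged = bool(best.success or grad_ok) and pd_ok and fmin < _PENALTY / 2
        return SemResults(self, theta, fmin, converged, diagnostics={
            "n_starts": n_starts,
            "optimizer_message": str(best.message),
            "grad_inf_norm": float(np.max(np.abs(best.jac))),
        })

    # -- simulation ----------------------------------------------------------

    def simulate(self, theta, n: int, seed: int = 0) -> pd.DataFrame:
        return sample_covariance_dataset(self.spec, theta, n, seed)


def sample_covariance_dataset(
    spec: SemSpec, theta_true, n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal rows with the model-implied covariance.

    The population covariance of the returned table equals
    ``spec.implied_covariance(theta_true)``; rejected when that matrix is
    not positive-definite.  Deterministic in (spec, theta_true, n, seed).
    """
    sigma = spec.implied_covariance(theta_true)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied covariance is not positive-definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, sigma.shape[0]))
    return pd.DataFrame(z @ L.T, columns=spec.observed)


class SemResults:
    """Fitted-model results: estimates, fit indices, standardized solution."""

    def __init__(self, model: SemModel, theta: np.ndarray, fmin: float,
                 converged: bool, diagnostics: dict):
        self.model = model
        self.spec = model.spec
        self.theta = theta
        self.fmin = fmin
        self.converged = converged
        self.diagnostics = diagnostics

        self.nobs = model.nobs
        self.df = self.spec.df
        self.chi_square = max((self.nobs - 1) * fmin, 0.0)
        from scipy.stats import chi2 as _chi2

        self.p_value = float(_chi2.sf(self.chi_square, self.df)) if self.df > 0 else np.nan
        self.implied_cov = self.spec.implied_covariance(theta)
        self.sample_cov = model.S
        self._fit_indices()

    # -- parameter access ----------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            self.theta, index=[p.label for p in self.spec.free_parameters], name="estimate"
        )

    def theta_dict(self) -> dict[str, float]:
        return dict(self.params)

    # -- fit indices ---------------------------------------------------------

    def _fit_indices(self) -> None:
        S, sigma = self.sample_cov, self.implied_cov
        p = S.shape[0]
        W = np.linalg.solve(sigma, S)        # Sigma^-1 S
        num = np.trace((W - np.eye(p)) @ (W - np.eye(p)))
        den = np.trace(W @ W)
        self.gfi = float(1.0 - num / den)

        if self.df > 0:
            self.agfi = float(1.0 - (p * (p + 1) / (2.0 * self.df)) * (1.0 - self.gfi))
            self.rmsea = float(
                np.sqrt(max(self.chi_square - self.df, 0.0) / (self.df * (self.nobs - 1)))
            )
        else:
            self.agfi = np.nan
            self.rmsea = np.nan

        chi_b, df_b = independence_fit(S, self.nobs)
        self.baseline_chi_square, self.baseline_df = chi_b, df_b
        denom = max(chi_b - df_b, self.chi_square - self.df, 0.0)
        self.cfi = 1.0 if denom == 0 else float(
            1.0 - max(self.chi_square - self.df, 0.0) / denom
        )

    # -- standardized solution -------------------------------------------------

    def standardized(self) -> pd.DataFrame:
        """Standardized coefficients (unit-variance source and target)."""
        C = self.spec.full_covariance(self.theta)
        names = self.spec.variables
        sd = {v: float(np.sqrt(max(C[i, i], 0.0))) for i, v in enumerate(names)}
        pos = {id(p): i for i, p in enumerate(self.spec.free_parameters)}

        rows = []
        for p_ in self.spec.parameters:
            est = (
                float(self.theta[pos[id(p_)]])
                if p_.free
                else float(p_.value if p_.value is not None else 0.0)
            )
            if p_.kind in ("loading", "path"):
                src, tgt = p_.lhs, p_.rhs
                if sd[tgt] <= 0:
                    raise ValueError(f"zero implied variance for {tgt!r}")
                std = est * sd[src] / sd[tgt]
            elif p_.kind == "cov":
                denom = sd[p_.lhs] * sd[p_.rhs]
                std = est / denom if denom > 0 else np.nan
            else:
                v = sd[p_.lhs] ** 2
                std = est / v if v > 0 else np.nan
            rows.append(
                {
                    "kind": p_.kind,
                    "lhs": p_.lhs,
                    "rhs": p_.rhs,
                    "free": p_.free,
                    "estimate": est,
                    "standardized": std,
                }
            )
        return pd.DataFrame(rows)

    # -- pruning ---------------------------------------------------------------

    def prune_paths(self, threshold: float = 0.1):
        """Spec copy with weak free structural paths removed.

        Free directed paths with |standardized coefficient| < threshold are
        dropped; a removal that would leave an observed variable untouched
        by every loading and path is retained and flagged.  Returns
        (new_spec, flagged_labels).
        """
        std = self.standardized()
        spec = self.spec.copy()
        flagged: list[str] = []
        for p_ in list(spec.paths):
            row = std[(std.kind == "path") & (std.lhs == p_.lhs) & (std.rhs == p_.rhs)]
            s = float(row["standardized"].iloc[0])
            if not (p_.free and abs(s) < threshold):
                continue
            backup = spec.paths
            spec.paths = [q for q in backup if q is not p_]
            if any(not spec._touches(v) for v in spec.observed):
                spec.paths = backup          # removal would orphan a variable
                flagged.append(p_.label)
        return spec, flagged

    # -- reporting -------------------------------------------------------------

    def index_line(self) -> str:
        return (
            f"chi2 = {self.chi_square:.2f} (df = {self.df}, p = {self.p_value:.3g}), "
            f"GFI = {self.gfi:.3f}, AGFI = {self.agfi:.3f}, "
            f"CFI = {self.cfi:.3f}, RMSEA = {self.rmsea:.3f}"
        )

    def summary(self) -> str:
        std = self.standardized()
        lines = [
            "Covariance-structure model (ML estimation)",
            "=" * 58,
            f"observed: {len(self.spec.observed)}   latent: {len(self.spec.latents)}   "
            f"N = {self.nobs}   free parameters = {self.spec.n_free}",
            f"converged: {self.converged}",
            self.index_line(),
            "-" * 58,
            f"{'parameter':<28}{'estimate':>12}{'std.':>12}",
        ]
        op = {"loading": "=~", "path": "~>", "cov": "~~", "var": "~~"}
        for _, r in std.iterrows():
            tag = "" if r["free"] else " (fixed)"
            lines.append(
                f"{r['lhs'] + ' ' + op[r['kind']] + ' ' + r['rhs']:<28}"
                f"{r['estimate']:>12.3f}{r['standardized']:>12.3f}{tag}"
            )
        return "\n".join(lines)


def independence_fit(S: np.ndarray, nobs: int) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal) baseline model.

    The ML solution of the independence model is Sigma = diag(S), giving
    F_b = sum(ln S_ii) - ln|S| in closed form.
    """
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    f_b = float(np.sum(np.log(np.diag(S))) - logdet)
    return max((nobs - 1) * f_b, 0.0), p * (p - 1) // 2


def fit_indices(results: SemResults) -> tuple[float, float, float, float]:
    """(GFI, AGFI, CFI, RMSEA) of a fitted model; AGFI/RMSEA are NaN at df=0."""
    return results.gfi, results.agfi, results.cfi, results.rmsea


def rmsea_from_stats(chi_square: float, df: int, nobs: int) -> float:
    """RMSEA from summary statistics: sqrt(max(chi2-df,0) / (df*(N-1)))."""
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (nobs - 1))))


def agfi_from_gfi(gfi: float, df: int, p: int) -> float:
    """AGFI from GFI: 1 - [p(p+1) / (2 df)] (1 - GFI)."""
    if df <= 0:
        raise ValueError("AGFI undefined for df <= 0")
    return float(1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi))
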