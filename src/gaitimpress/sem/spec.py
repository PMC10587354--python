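"""Declarative specification of covariance-structure (SEM) models.

A :class:`SemSpec` lists observed variables, latent variables, loadings,
directed structural paths, and (co)variances.  Internally the model is the
reticular-action formulation: collect all variables (observed + latent) in
one vector v with

    v = A v + u,   Cov(u) = S0,   Sigma = F (I - A)^-1 S0 (I - A)^-T F^T

where A holds directed coefficients (loadings and paths), S0 the symmetric
variances/covariances of exogenous terms and residuals, and F selects the
observed variables.

Identification conventions (configurable per latent): multi-indicator
latents fix their first loading to 1; single-indicator latents fix the
loading to 1 and the indicator's error variance to 0, making the indicator
the latent up to scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass
class Parameter:
    """One loading, path, covariance, or variance entry."""

    kind: str              # 'loading' | 'path' | 'cov' | 'var'
    lhs: str               # loading: latent; path: source; cov/var: variable
    rhs: str               # loading: indicator; path: target; cov: other variable
    free: bool = True
    value: float | None = None   # fixed value, or start value for free params

    @property
    def label(self) -> str:
        op = {"loading": "=~", "path": "~>", "cov": "~~", "var": "~~"}[self.kind]
        return f"{self.lhs}{op}{self.rhs}"


class SemSpec:
    """Model specification with builder methods.

    Parameters
    ----------
    observed : list[str]
        Ordered observed-variable names (defines the row order of S).
    """

    def __init__(self, observed: list[str]):
        self.observed: list[str] = list(observed)
        self.latents: list[str] = []
        self.loadings: list[Parameter] = []
        self.paths: list[Parameter] = []
        self.covariances: list[Parameter] = []
        self._variances: dict[str, Parameter] = {}
        for v in self.observed:
            self._variances[v] = Parameter("var", v, v, free=True)

    # -- builders ------------------------------------------------------------

    def add_latent(
        self,
        name: str,
        indicators: list[str],
        loadings: list[float | None] | None = None,
        fix_first: bool = True,
    ) -> "SemSpec":
        """Add a latent with its measurement loadings.

        A single indicator gets loading fixed to 1 and error variance fixed
        to 0 (the indicator is the latent up to scale).  Otherwise the first
        loading is fixed to 1 unless ``fix_first=False``.
        """
        if name in self.latents:
            raise ValueError(f"duplicate latent {name!r}")
        self.latents.append(name)
        self._variances[name] = Parameter("var", name, name, free=True)
        single = len(indicators) == 1
        for i, ind in enumerate(indicators):
            if ind not in self.observed:
                raise ValueError(f"indicator {ind!r} is not an observed variable")
            fixed = single or (fix_first and i == 0)
            start = None if fixed else (loadings[i] if loadings else None)
            self.loadings.append(
                Parameter("loading", name, ind, free=not fixed, value=1.0 if fixed else start)
            )
        if single:
            self.fix_variance(indicators[0], 0.0)
        return self

    def add_path(self, source: str, target: str, value: float | None = None,
                 free: bool = True) -> "SemSpec":
        self._check_var(source)
        self._check_var(target)
        self.paths.append(Parameter("path", source, target, free=free, value=value))
        return self

    def add_covariance(self, a: str, b: str, value: float | None = None,
                       free: bool = True) -> "SemSpec":
        self._check_var(a)
        self._check_var(b)
        if a == b:
            raise ValueError("use variances for a == b")
        self.covariances.append(Parameter("cov", a, b, free=free, value=value))
        return self

    def fix_variance(self, name: str, value: float) -> "SemSpec":
        self._check_var(name)
        self._variances[name] = Parameter("var", name, name, free=False, value=value)
        return self

    def _check_var(self, name: str) -> None:
        if name not in self.observed and name not in self.latents:
            raise ValueError(f"unknown variable {name!r}")

    # -- bookkeeping ---------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return self.observed + self.latents

    @property
    def variances(self) -> list[Parameter]:
        return [self._variances[v] for v in self.variables]

    @property
    def parameters(self) -> list[Parameter]:
        return self.loadings + self.paths + self.covariances + self.variances

    @property
    def free_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if p.free]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def copy(self) -> "SemSpec":
        import copy as _copy

        return _copy.deepcopy(self)

    def validate(self, expected_df: int | None = None) -> list[str]:
        """Return a list of diagnostics (empty when everything checks out)."""
        issues = []
        p = len(self.observed)
        for v in self.observed:
            if not self._touches(v):
                issues.append(f"observed variable {v!r} appears in no loading or path")
        labels = [q.label for q in self.free_parameters]
        if len(labels) != len(set(labels)):
            issues.append("duplicate free-parameter labels")
        if self.n_free > p * (p + 1) // 2:
            issues.append(
                f"{self.n_free} free parameters exceed the {p * (p + 1) // 2} "
                "observed moments (df < 0)"
            )
        if expected_df is not None and self.df != expected_df:
            issues.append(f"spec df {self.df} differs from expected df {expected_df}")
        return issues

    def _touches(self, v: str) -> bool:
        return any(q.rhs == v for q in self.loadings) or any(
            v in (q.lhs, q.rhs) for q in self.paths
        )

    # -- RAM assembly ----------------------------------------------------------

    def assemble(self, theta: np.ndarray | dict[str, float]):
        """Build (A, S0) from a free-parameter vector or label->value map."""
        if isinstance(theta, dict):
            vec = np.array([theta[p.label] for p in self.free_parameters], dtype=float)
        else:
            vec = np.asarray(theta, dtype=float)
            if vec.shape != (self.n_free,):
                raise ValueError(f"theta must have length {self.n_free}")
        pos = {id(p): i for i, p in enumerate(self.free_parameters)}
        idx = {v: i for i, v in enumerate(self.variables)}
        n = len(self.variables)
        A = np.zeros((n, n))
        S0 = np.zeros((n, n))

        def val(p: Parameter) -> float:
            if p.free:
                return float(vec[pos[id(p)]])
            return float(p.value if p.value is not None else 0.0)

        for p in self.loadings:
            A[idx[p.rhs], idx[p.lhs]] = val(p)   # indicator <- latent
        for p in self.paths:
            A[idx[p.rhs], idx[p.lhs]] = val(p)   # target <- source
        for p in self.covariances:
            S0[idx[p.lhs], idx[p.rhs]] = S0[idx[p.rhs], idx[p.lhs]] = val(p)
        for p in self.variances:
            S0[idx[p.lhs], idx[p.lhs]] = val(p)
        return A, S0

    def implied_covariance(self, theta) -> np.ndarray:
        """Model-implied covariance of the observed variables."""
        A, S0 = self.assemble(theta)
        n = A.shape[0]
        B = np.eye(n) - A
        try:
            Binv = np.linalg.solve(B, np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular (I - A): structural system not invertible") from exc
        C = Binv @ S0 @ Binv.T
        k = len(self.observed)
        return C[:k, :k]

    def full_covariance(self, theta) -> np.ndarray:
        """Implied covariance of all variables (observed + latent)."""
        A, S0 = self.assemble(theta)
        n = A.shape[0]
        Binv = np.linalg.solve(np.eye(n) - A, np.eye(n))
        return Binv @ S0 @ Binv.T

    # -- serialization ---------------------------------------------------------

    def to_text(self) -> str:
        doc = {
            "observed": self.observed,
            "latents": self.latents,
            "loadings": [
                {"latent": p.lhs, "indicator": p.rhs, "free": p.free, "value": p.value}
                for p in self.loadings
            ],
            "paths": [
                {"source": p.lhs, "target": p.rhs, "free": p.free, "value": p.value}
                for p in self.paths
            ],
            "covariances": [
                {"a": p.lhs, "b": p.rhs, "free": p.free, "value": p.value}
                for p in self.covariances
            ],
            "variances": [
                {"variable": p.lhs, "free": p.free, "value": p.value}
                for p in self.variances
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_text(cls, text: str) -> "SemSpec":
        doc = yaml.safe_load(text)
        spec = cls(doc["observed"])
        spec.latents = list(doc.get("latents", []))
        for name in spec.latents:
            spec._variances[name] = Parameter("var", name, name, free=True)
        spec.loadings = [
            Parameter("loading", d["latent"], d["indicator"], d["free"], d.get("value"))
            for d in doc.get("loadings", [])
        ]
        spec.paths = [
            Parameter("path", d["source"], d["target"], d["free"], d.get("value"))
            for d in doc.get("paths", [])
        ]
        spec.covariances = [
            Parameter("cov", d["a"], d["b"], d["free"], d.get("value"))
            for d in doc.get("covariances", [])
        ]
        for d in doc.get("variances", []):
            spec._variances[d["variable"]] = Parameter(
                "var", d["variable"], d["variable"], d["free"], d.get("value")
            )
        return spec
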