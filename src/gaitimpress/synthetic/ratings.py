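"""Synthetic observer ratings from a latent linear impression model.

Each observer i rates each animation j on two 7-point Likert items
(attractiveness, femininity).  The latent score is

    s_ij = sum_f w_f * x_f(j) + b_i + eps_ij

with feature weights ``w``, a per-observer additive bias ``b_i ~ N(0,
observer_bias_sd)``, and draw noise ``eps_ij ~ N(0, latent_noise_sd)``.
Fixed ordered thresholds shared by all observers discretize the latent into
categories 1..7.  This is the simplest mechanism producing observer-level
variance comparable to pooling ~60 observers over ~34 animations per
condition (≈ 2040 rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (-1.25, -0.75, -0.25, 0.25, 0.75, 1.25)


@dataclass
class ImpressionGenModel:
    """Ground-truth latent impression model for rating generation."""

    feature_weights_attract: dict[str, float] = field(default_factory=dict)
    feature_weights_fem: dict[str, float] = field(default_factory=dict)
    latent_noise_sd: float = 1.0
    likert_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_observers: int = 60
    observer_bias_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        th = np.asarray(self.likert_thresholds, dtype=float)
        if len(th) != 6 or np.any(np.diff(th) <= 0):
            raise ValueError("likert_thresholds must be 6 strictly increasing cutpoints")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.latent_noise_sd < 0 or self.observer_bias_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def from_standardized(
        cls,
        features: pd.DataFrame,
        weights_attract: dict[str, float],
        weights_fem: dict[str, float] | None = None,
        **kwargs,
    ) -> "ImpressionGenModel":
        """Build a model whose weights apply to z-scored features.

        The given weights are per standard deviation of each feature in
        ``features`` and are converted to raw-scale coefficients (the
        implied constant shift is absorbed because the thresholds are
        symmetric around the resulting mean latent).
        """
        weights_fem = weights_fem if weights_fem is not None else dict(weights_attract)

        def convert(wz: dict[str, float]) -> dict[str, float]:
            out = {}
            for name, w in wz.items():
                sd = float(features[name].std(ddof=1))
                if sd <= 0:
                    raise ValueError(f"feature {name!r} has zero variance")
                out[name] = w / sd
            return out

        model = cls(
            feature_weights_attract=convert(weights_attract),
            feature_weights_fem=convert(weights_fem),
            **kwargs,
        )
        # center the latent by shifting thresholds to the mean raw score
        mu = float(
            np.mean(
                [
                    sum(w * row[n] for n, w in model.feature_weights_attract.items())
                    for _, row in features.iterrows()
                ]
            )
        )
        model.likert_thresholds = tuple(t + mu for t in DEFAULT_THRESHOLDS)
        return model


def _discretize(latent: np.ndarray, thresholds) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(thresholds, dtype=float), latent, side="left")


def generate_ratings(features: pd.DataFrame, model: ImpressionGenModel) -> pd.DataFrame:
    """Simulate the rating table: one row per (observer, animation).

    ``features`` must have one row per animation with an ``animation_id``
    column (or a default one is derived from walker/trial/condition) and a
    column for every feature named in the weight maps.  Output columns:
    observer_id, animation_id, attractiveness, femininity.  Deterministic
    in (features, model, seed).
    """
    model.validate()
    feats = features.copy()
    if "animation_id" not in feats.columns:
        feats["animation_id"] = [
            f"{r.walker_id}_{r.trial_id}_{r.condition}" for r in feats.itertuples()
        ]
    for wmap in (model.feature_weights_attract, model.feature_weights_fem):
        for name in wmap:
            if name not in feats.columns:
                raise KeyError(f"unknown feature name in weight map: {name!r}")

    rng = np.random.default_rng(model.seed)
    n_anim = len(feats)
    n_obs = model.n_observers
    bias = rng.normal(0.0, model.observer_bias_sd, n_obs) if model.observer_bias_sd > 0 else np.zeros(n_obs)

    def latent_base(wmap: dict[str, float]) -> np.ndarray:
        base = np.zeros(n_anim)
        for name, w in wmap.items():
            base += w * feats[name].to_numpy(dtype=float)
        return base

    base_a = latent_base(model.feature_weights_attract)
    base_f = latent_base(model.feature_weights_fem)

    rows = []
    for i in range(n_obs):
        eps_a = rng.normal(0.0, model.latent_noise_sd, n_anim) if model.latent_noise_sd > 0 else 0.0
        eps_f = rng.normal(0.0, model.latent_noise_sd, n_anim) if model.latent_noise_sd > 0 else 0.0
        a = _discretize(base_a + bias[i] + eps_a, model.likert_thresholds)
        f = _discretize(base_f + bias[i] + eps_f, model.likert_thresholds)
        rows.append(
            pd.DataFrame(
                {
                    "observer_id": i,
                    "animation_id": feats["animation_id"].to_numpy(),
                    "attractiveness": a,
                    "femininity": f,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def drop_rows_at_random(
    ratings: pd.DataFrame, n_drop: int, seed: int = 0
) -> pd.DataFrame:
    """Remove ``n_drop`` rating rows uniformly at random (missing responses)."""
    rng = np.random.default_rng(seed)
    keep = np.ones(len(ratings), dtype=bool)
    keep[rng.choice(len(ratings), size=n_drop, replace=False)] = False
    return ratings.loc[keep].reset_index(drop=True)
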