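"""The four packaged gait-attractiveness models (B1, B2, H1, H2).

Two model families per footwear condition:

* B1 / H1 -- two gait-silhouette factors: trunk silhouette (Silhouette-T)
  and head silhouette (Silhouette-H) predicting the per-observer
  attractiveness and femininity ratings;
* B2 / H2 -- physique (BMI), Silhouette-T, and a health factor (cadence,
  knee extension) with all latent covariances free.

The free/fixed path sets are reconstructed from the published model
descriptions and their printed degrees of freedom (2, 9, 3, 3).  Where the
prose alone under-determines the reconstruction, one extra free parameter
is chosen to reproduce the printed df: B2 and H2 carry a free disturbance
covariance between the two outcome ratings, and H1 a Silhouette-H ->
attractiveness path.  ``SemSpec.validate(expected_df=...)`` surfaces any
residual mismatch instead of silently adjusting it.

``TRUE_PARAMS`` holds a plausible population parameterization per model
(standardized-scale values near the published standardized estimates where
available) used for simulation-based parameter-recovery checks.
"""

from __future__ import annotations

from .spec import SemSpec

MODEL_NAMES = ("B1", "B2", "H1", "H2")

#: Printed summary statistics of the fitted models (chi2, df, N, GFI, AGFI,
#: CFI, RMSEA) used for closure checks of the index implementation.
PUBLISHED_FIT = {
    "B1": {"chi_square": 34.63, "df": 2, "nobs": 2037, "gfi": 0.993,
           "agfi": 0.949, "cfi": 0.965, "rmsea": 0.090, "p_observed": 5},
    "B2": {"chi_square": 80.30, "df": 9, "nobs": 2037, "gfi": 0.989,
           "agfi": 0.965, "cfi": 0.940, "rmsea": 0.062, "p_observed": 7},
    "H1": {"chi_square": 32.43, "df": 3, "nobs": 2038, "gfi": 0.994,
           "agfi": 0.968, "cfi": 0.971, "rmsea": 0.069, "p_observed": 5},
    "H2": {"chi_square": 54.71, "df": 3, "nobs": 2038, "gfi": 0.991,
           "agfi": 0.937, "cfi": 0.951, "rmsea": 0.092, "p_observed": 6},
}

EXPECTED_DF = {name: PUBLISHED_FIT[name]["df"] for name in MODEL_NAMES}


def builtin_model(name: str) -> SemSpec:
    """Return the packaged spec for one of B1, B2, H1, H2."""
    if name == "B1":
        spec = SemSpec(
            ["lumbar_curvature", "backward_arm_swing", "forward_head_tilt",
             "attractiveness", "femininity"]
        )
        spec.add_latent("SilhouetteT", ["lumbar_curvature", "backward_arm_swing"])
        spec.add_latent("SilhouetteH", ["forward_head_tilt"])
        spec.add_covariance("SilhouetteT", "SilhouetteH")
        spec.add_path("SilhouetteT", "attractiveness")
        spec.add_path("SilhouetteH", "attractiveness")
        spec.add_path("SilhouetteH", "femininity")
        # positive mutual relationship: nonrecursive directed pair
        spec.add_path("attractiveness", "femininity")
        spec.add_path("femininity", "attractiveness")
        return spec

    if name == "B2":
        spec = SemSpec(
            ["bmi", "lumbar_curvature", "backward_arm_swing", "cadence",
             "knee_extension", "attractiveness", "femininity"]
        )
        spec.add_latent("Physique", ["bmi"])
        spec.add_latent("SilhouetteT", ["lumbar_curvature", "backward_arm_swing"])
        spec.add_latent("Health", ["cadence", "knee_extension"])
        spec.add_covariance("Physique", "SilhouetteT")
        spec.add_covariance("Physique", "Health")
        spec.add_covariance("SilhouetteT", "Health")
        spec.add_path("Physique", "attractiveness")
        spec.add_path("Physique", "femininity")
        spec.add_path("SilhouetteT", "attractiveness")
        spec.add_path("attractiveness", "femininity")
        # disturbance covariance between the outcomes (df bookkeeping: 9)
        spec.add_covariance("attractiveness", "femininity")
        return spec

    if name == "H1":
        spec = SemSpec(
            ["backward_arm_swing", "forward_head_tilt", "horizontal_head_shake",
             "attractiveness", "femininity"]
        )
        spec.add_latent("SilhouetteT", ["backward_arm_swing"])
        spec.add_latent("SilhouetteH", ["forward_head_tilt", "horizontal_head_shake"])
        spec.add_covariance("SilhouetteT", "SilhouetteH")
        spec.add_path("SilhouetteT", "attractiveness")
        spec.add_path("SilhouetteT", "femininity")
        spec.add_path("SilhouetteH", "attractiveness")
        spec.add_path("attractiveness", "femininity")  # printed -0.21
        return spec

    if name == "H2":
        spec = SemSpec(
            ["bmi", "backward_arm_swing", "cadence", "knee_extension",
             "attractiveness", "femininity"]
        )
        spec.add_latent("Physique", ["bmi"])
        spec.add_latent("SilhouetteT", ["backward_arm_swing"])
        spec.add_latent("Health", ["cadence", "knee_extension"])
        spec.add_covariance("Physique", "SilhouetteT")
        spec.add_covariance("Physique", "Health")
        spec.add_covariance("SilhouetteT", "Health")
        spec.add_path("Physique", "attractiveness")
        spec.add_path("Health", "femininity")
        spec.add_path("SilhouetteT", "attractiveness")
        spec.add_path("SilhouetteT", "femininity")
        spec.add_path("attractiveness", "femininity")
        spec.add_path("femininity", "attractiveness")
        spec.add_covariance("attractiveness", "femininity")
        return spec

    raise ValueError(f"unknown builtin model {name!r}; choose from {MODEL_NAMES}")


#: Plausible population parameter values per builtin spec (label -> value),
#: used by simulation-based recovery tests.
TRUE_PARAMS: dict[str, dict[str, float]] = {
    "B1": {
        "SilhouetteT=~backward_arm_swing": 0.80,
        "SilhouetteT~~SilhouetteH": 0.50,
        "SilhouetteT~>attractiveness": 0.55,
        "SilhouetteH~>attractiveness": 0.25,
        "SilhouetteH~>femininity": 0.40,
        "attractiveness~>femininity": 0.45,
        "femininity~>attractiveness": 0.20,
        "lumbar_curvature~~lumbar_curvature": 0.50,
        "backward_arm_swing~~backward_arm_swing": 0.40,
        "attractiveness~~attractiveness": 0.40,
        "femininity~~femininity": 0.35,
        "SilhouetteT~~SilhouetteT": 1.00,
        "SilhouetteH~~SilhouetteH": 1.00,
    },
    "B2": {
        "SilhouetteT=~backward_arm_swing": 0.80,
        "Health=~knee_extension": -0.60,
        "Physique~~SilhouetteT": -0.35,
        "Physique~~Health": 0.80,
        "SilhouetteT~~Health": -0.30,
        "Physique~>attractiveness": -0.40,
        "Physique~>femininity": -0.20,
        "SilhouetteT~>attractiveness": 0.50,
        "attractiveness~>femininity": 0.70,
        "attractiveness~~femininity": 0.15,
        "lumbar_curvature~~lumbar_curvature": 0.60,
        "backward_arm_swing~~backward_arm_swing": 0.40,
        "cadence~~cadence": 0.45,
        "knee_extension~~knee_extension": 0.50,
        "attractiveness~~attractiveness": 0.50,
        "femininity~~femininity": 0.35,
        "Physique~~Physique": 1.00,
        "SilhouetteT~~SilhouetteT": 1.00,
        "Health~~Health": 1.00,
    },
    "H1": {
        "SilhouetteH=~horizontal_head_shake": -0.60,
        "SilhouetteT~~SilhouetteH": 0.55,
        "SilhouetteT~>attractiveness": 0.60,
        "SilhouetteT~>femininity": 0.90,
        "SilhouetteH~>attractiveness": 0.25,
        "attractiveness~>femininity": -0.21,
        "forward_head_tilt~~forward_head_tilt": 0.50,
        "horizontal_head_shake~~horizontal_head_shake": 0.60,
        "attractiveness~~attractiveness": 0.40,
        "femininity~~femininity": 0.35,
        "SilhouetteT~~SilhouetteT": 1.00,
        "SilhouetteH~~SilhouetteH": 1.00,
    },
    "H2": {
        "Health=~knee_extension": -0.60,
        "Physique~~SilhouetteT": -0.30,
        "Physique~~Health": 0.75,
        "SilhouetteT~~Health": -0.25,
        "Physique~>attractiveness": -0.45,
        "Health~>femininity": -0.40,
        "SilhouetteT~>attractiveness": 0.50,
        "SilhouetteT~>femininity": 0.60,
        "attractiveness~>femininity": 0.35,
        "femininity~>attractiveness": 0.20,
        "attractiveness~~femininity": 0.10,
        "cadence~~cadence": 0.40,
        "knee_extension~~knee_extension": 0.50,
        "attractiveness~~attractiveness": 0.45,
        "femininity~~femininity": 0.35,
        "Physique~~Physique": 1.00,
        "SilhouetteT~~SilhouetteT": 1.00,
        "Health~~Health": 1.00,
    },
}
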