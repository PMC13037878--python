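"""Aging-trajectory statistics on cohort metric tables.

Cross-sectional and longitudinal age effects are estimated with linear models:
a random intercept per subject absorbs repeated scans (REML mixed model) and
the fit reduces exactly to ordinary least squares when every subject has one
scan.  Mouse ages are placed on a human-equivalent scale by linear
interpolation through two anchor pairs (3 mo ~ 18 y, 20 mo ~ 70 y by default)
before the cross-species model, which tests species, age, and their
interaction while controlling for sex.

Inference uses Wald F tests (squared coefficient z ratios).  With repeated
scans the denominator degrees of freedom are containment-style
(n_obs - rank(X) - n_subjects + 1); with purely cross-sectional data they are
the exact OLS residual df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-species age mapping


@dataclass(frozen=True)
class AgeMapping:
    """Two anchor pairs defining an affine mouse-months -> human-years map."""

    mouse_anchor_young: float = 3.0
    human_anchor_young: float = 18.0
    mouse_anchor_old: float = 20.0
    human_anchor_old: float = 70.0

    def __post_init__(self) -> None:
        if not (self.mouse_anchor_young < self.mouse_anchor_old):
            raise ValueError("mouse anchors must be strictly increasing")
        if not (self.human_anchor_young < self.human_anchor_old):
            raise ValueError("human anchors must be strictly increasing")


def map_mouse_age(age_months, mapping: AgeMapping = AgeMapping()):
    """Human-equivalent years for mouse ages, by anchor interpolation.

    The map is affine, so it extrapolates linearly outside the anchors (a
    warning is logged when it does).
    """
    age = np.asarray(age_months, dtype=float)
    lo, hi = mapping.mouse_anchor_young, mapping.mouse_anchor_old
    if np.any((age < lo) | (age > hi)):
        logger.warning("mouse age(s) outside anchor band [%g, %g]; extrapolating", lo, hi)
    slope = (mapping.human_anchor_old - mapping.human_anchor_young) / (hi - lo)
    out = mapping.human_anchor_young + (age - lo) * slope
    return float(out) if np.isscalar(age_months) else out


# ---------------------------------------------------------------------------
# design helpers


def _sex_code(sex: pd.Series) -> np.ndarray:
    """Centered binary sex covariate (F/M or 0/1 accepted)."""
    s = sex.astype(str).str.upper().map({"F": -0.5, "M": 0.5, "0": -0.5, "1": 0.5})
    if s.isna().any():
        raise ValueError("sex must be coded F/M (or 0/1)")
    code = s.to_numpy(dtype=float)
    return code - code.mean()


def _wald_terms(params, bses, names, df2) -> dict[str, dict[str, float]]:
    out = {}
    for name, b, se in zip(names, params, bses):
        if se == 0 or not np.isfinite(se):
            f_val, p_val = (0.0, 1.0) if b == 0 else (np.inf, 0.0)
        else:
            f_val = float((b / se) ** 2)
            p_val = float(sps.f.sf(f_val, 1, df2))
        out[name] = {"beta": float(b), "se": float(se), "F": f_val, "df": (1, int(df2)), "p": p_val}
    return out


def _fit_linear(endog: np.ndarray, exog: np.ndarray, groups: np.ndarray | None):
    """REML random-intercept fit when groups repeat, OLS otherwise.

    Returns (params, bses, df2, model_kind).
    """
    n, rank = exog.shape[0], np.linalg.matrix_rank(exog)
    repeats = groups is not None and pd.Series(groups).duplicated().any()
    if repeats:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(endog, exog, groups=groups).fit(reml=True)
        n_subj = len(set(groups))
        df2 = max(n - rank - n_subj + 1, 1)
        return np.asarray(res.fe_params), np.asarray(res.bse_fe), df2, "mixed"
    res = sm.OLS(endog, exog).fit()
    return np.asarray(res.params), np.asarray(res.bse), n - rank, "ols"


# ---------------------------------------------------------------------------
# age trajectories


def fit_age_trajectory(
    cohort: pd.DataFrame,
    response: str = "segregation",
    fixed: tuple[str, ...] = ("age", "sex"),
    random_intercept: bool = True,
) -> dict:
    """Age slope of a cohort metric, with optional sex covariate and a random
    intercept per subject when any subject has repeated scans.

    Returns a dict with raw and standardized age slopes, per-term Wald F
    tests, and fit provenance (formula, n, df).
    """
    needed = {response, "subject_id", *fixed}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks column(s): {sorted(missing)}")
    df = cohort.dropna(subset=[response]).reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    if len(np.unique(df["age"])) < 2:
        raise ValueError("need >= 2 distinct ages to estimate an age slope")

    if np.ptp(y) == 0:
        return {
            "beta_age": 0.0,
            "beta_age_std": 0.0,
            "terms": {"age": {"beta": 0.0, "se": 0.0, "F": 0.0, "df": (1, len(y) - 2), "p": 1.0}},
            "n": len(y),
            "model": "degenerate-constant-response",
        }

    cols = [np.ones(len(df))]
    names = ["const"]
    if "age" in fixed:
        cols.append(df["age"].to_numpy(dtype=float))
        names.append("age")
    if "sex" in fixed:
        cols.append(_sex_code(df["sex"]))
        names.append("sex")
    exog = np.column_stack(cols)

    groups = df["subject_id"].to_numpy() if random_intercept else None
    try:
        params, bses, df2, kind = _fit_linear(y, exog, groups)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular fit: {exc}") from exc
    terms = _wald_terms(params, bses, names, df2)
    beta_age = terms.get("age", {}).get("beta", 0.0)
    sd_age = float(df["age"].std(ddof=1))
    sd_y = float(np.std(y, ddof=1))
    return {
        "beta_age": beta_age,
        "se_age": terms.get("age", {}).get("se"),
        "beta_age_std": beta_age * sd_age / sd_y,
        "terms": terms,
        "n": len(y),
        "n_subjects": int(df["subject_id"].nunique()),
        "model": kind,
        "formula": f"{response} ~ {' + '.join(names[1:])} (+ subject intercept)"
        if kind == "mixed"
        else f"{response} ~ {' + '.join(names[1:])}",
    }


def cross_species_model(
    mouse: pd.DataFrame,
    human: pd.DataFrame,
    mapping: AgeMapping = AgeMapping(),
    response: str = "segregation",
) -> dict:
    """Species, age, and species x age effects on a metric, controlling sex.

    Mouse ages are mapped to human-equivalent years, the common-scale age is
    z-scored within the combined sample, and species is coded symmetrically
    (mouse -0.5, human +0.5), so swapping species labels flips the species and
    interaction coefficients without touching the age main effect.
    Per-species standardized slopes come from the interaction
    parameterization refit on the z-scored response.
    """
    if mouse.empty or human.empty:
        raise ValueError("both species tables must be non-empty")
    m = mouse.copy()
    h = human.copy()
    m["age_common"] = map_mouse_age(m["age"].to_numpy(), mapping)
    h["age_common"] = h["age"].astype(float)
    m["species_code"] = -0.5
    h["species_code"] = 0.5
    m["subject_id"] = "m_" + m["subject_id"].astype(str)
    h["subject_id"] = "h_" + h["subject_id"].astype(str)
    df = pd.concat([m, h], ignore_index=True).dropna(subset=[response])
    for tab, name in ((m, "mouse"), (h, "human")):
        if tab["age_common"].nunique() < 2:
            raise ValueError(f"{name} table lacks age variation")

    age = df["age_common"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std(ddof=1)
    spec = df["species_code"].to_numpy(dtype=float)
    sex = _sex_code(df["sex"])
    y = df[response].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(df)), age_z, spec, age_z * spec, sex])
    names = ["const", "age", "species", "age_x_species", "sex"]
    groups = df["subject_id"].to_numpy()
    params, bses, df2, kind = _fit_linear(y, exog, groups)
    terms = _wald_terms(params, bses, names, df2)

    y_z = (y - y.mean()) / y.std(ddof=1)
    params_std, *_ = _fit_linear(y_z, exog, groups)
    b_age_std, b_int_std = params_std[1], params_std[3]
    return {
        "main_age": terms["age"],
        "main_species": terms["species"],
        "interaction": terms["age_x_species"],
        "sex": terms["sex"],
        "beta_mouse_std": float(b_age_std - 0.5 * b_int_std),
        "beta_human_std": float(b_age_std + 0.5 * b_int_std),
        "n": len(df),
        "model": kind,
    }


# ---------------------------------------------------------------------------
# factorial designs


def _contrast_f(values: np.ndarray) -> tuple[float, float]:
    """One-sample F(1, n-1) for a per-subject contrast."""
    n = len(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if np.allclose(values.mean(), 0) else (np.inf, 0.0)
    t = values.mean() / (sd / np.sqrt(n))
    f_val = float(t**2)
    return f_val, float(sps.f.sf(f_val, 1, n - 1))


def factorial_anova(
    values,
    factor_a,
    factor_b,
    design: str = "between_subjects",
    subject=None,
) -> dict:
    """2 x 2 ANOVA: main effects of A and B and their interaction.

    ``between_subjects`` uses the classical two-way decomposition (type II sums
    of squares); ``repeated`` treats both factors as within-subject and tests
    each effect against its subject-by-effect error stratum, which for a 2 x 2
    design is a one-sample test on the per-subject contrast.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float)})
    df["A"] = np.asarray(factor_a)
    df["B"] = np.asarray(factor_b)
    levels_a, levels_b = sorted(df["A"].unique()), sorted(df["B"].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    counts = df.groupby(["A", "B"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("each of the four cells needs >= 2 observations")

    if design == "between_subjects":
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        fit = ols("y ~ C(A) * C(B)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        key = {"A": "C(A)", "B": "C(B)", "A_x_B": "C(A):C(B)"}
        return {
            name: {
                "F": float(tab.loc[row, "F"]),
                "df": (int(tab.loc[row, "df"]), int(tab.loc["Residual", "df"])),
                "p": float(tab.loc[row, "PR(>F)"]),
            }
            for name, row in key.items()
        }

    if design != "repeated":
        raise ValueError("design must be 'between_subjects' or 'repeated'")
    if subject is None:
        raise ValueError("repeated design requires subject labels")
    df["subject"] = np.asarray(subject)
    cells = df.pivot_table(index="subject", columns=["A", "B"], values="y", aggfunc="mean")
    if cells.isna().any().any():
        raise ValueError("repeated design requires every subject in every cell")
    a1b1 = cells[(levels_a[0], levels_b[0])].to_numpy()
    a1b2 = cells[(levels_a[0], levels_b[1])].to_numpy()
    a2b1 = cells[(levels_a[1], levels_b[0])].to_numpy()
    a2b2 = cells[(levels_a[1], levels_b[1])].to_numpy()
    n = len(cells)
    out = {}
    for name, contrast in (
        ("A", (a1b1 + a1b2 - a2b1 - a2b2) / 2.0),
        ("B", (a1b1 - a1b2 + a2b1 - a2b2) / 2.0),
        ("A_x_B", a1b1 - a1b2 - a2b1 + a2b2),
    ):
        f_val, p_val = _contrast_f(contrast)
        out[name] = {"F": f_val, "df": (1, n - 1), "p": p_val}
    return out
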