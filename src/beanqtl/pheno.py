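"""Trait descriptive statistics: means, ranges, GCV, broad-sense heritability,
combined-environment values, and the anthocyanin absorbance conversion.

Phenotype tables are long-format DataFrames with columns ``line``, ``trait``,
``environment`` and ``value``; parents, when present, live in a separate table
of the same layout. Heritability is computed on an entry-mean basis from a
two-way (line x environment) decomposition of line means:

    h^2 = sigma2_G / (sigma2_G + MS_GE / e) * 100,

with sigma2_G = (MS_G - MS_GE) / e truncated at zero; with a single value per
line and environment the G x E and residual components are confounded and
enter together through MS_GE. GCV is 100 * sigma_G / mean; single-environment
slices fall back to the phenotypic coefficient of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up

COMBINED = "combined"


def _validate_table(table: pd.DataFrame) -> None:
    missing = {"line", "trait", "environment", "value"} - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    if table.duplicated(["line", "trait", "environment"]).any():
        raise ValueError("duplicate (line, trait, environment) records")
    if not np.isfinite(table["value"]).all():
        raise ValueError("phenotype values must be finite")


def anthocyanin_content(a530, a657):
    """Anthocyanin (ug/g fresh weight) from paired absorbances: A530 - 0.25 * A657.

    Negative absorbances are invalid; a negative result is floored at zero
    with a warning (blank-dominated extract).
    """
    a530 = np.asarray(a530, dtype=float)
    a657 = np.asarray(a657, dtype=float)
    if np.any(a530 < 0) or np.any(a657 < 0):
        raise ValueError("absorbances must be non-negative")
    value = a530 - 0.25 * a657
    if np.any(value < 0):
        warnings.warn("negative anthocyanin estimate floored at 0")
        value = np.maximum(value, 0.0)
    return float(value) if value.ndim == 0 else value


def combine_environments(table: pd.DataFrame, label: str = COMBINED) -> pd.DataFrame:
    """Append a synthetic combined environment: per line and trait, the
    arithmetic mean over the environments with data.

    Existing combined rows are recomputed (idempotent); lines absent from
    every environment simply do not appear.
    """
    _validate_table(table)
    base = table[table["environment"] != label]
    combined = (
        base.groupby(["line", "trait"], as_index=False)["value"]
        .mean()
        .assign(environment=label)
    )
    out = pd.concat([base, combined[["line", "trait", "environment", "value"]]], ignore_index=True)
    return out


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    environment: str | None
    n_lines: int
    mean: float
    minimum: float
    maximum: float
    gcv: float
    h2: float  # percent; NaN for single-environment summaries


def variance_components(table: pd.DataFrame, trait: str) -> tuple[float, float, int, float]:
    """(sigma2_G, MS_GE, n_environments, grand mean) from line x environment data.

    Balanced data uses the exact closed-form two-way ANOVA; unbalanced data is
    reduced to lines observed in every environment (available-case) with a
    warning, via a statsmodels OLS fit of the additive model.
    """
    sub = table[(table["trait"] == trait) & (table["environment"] != COMBINED)]
    envs = sub["environment"].unique()
    if len(envs) < 2:
        raise ValueError("variance components require at least two environments")
    wide = sub.pivot(index="line", columns="environment", values="value")
    if wide.isna().any().any():
        warnings.warn("unbalanced phenotype data: restricting to complete lines")
        complete = wide.dropna()
        if len(complete) < 2:
            raise ValueError("fewer than two lines observed in every environment")
        long = complete.reset_index().melt(id_vars="line", var_name="environment", value_name="value")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols("value ~ C(line) + C(environment)", data=long).fit()
        aov = anova_lm(fit, typ=2)
        ms_g = aov.loc["C(line)", "sum_sq"] / aov.loc["C(line)", "df"]
        ms_ge = aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]
        e = len(envs)
        grand = float(complete.to_numpy().mean())
    else:
        Y = wide.to_numpy()
        n_l, e = Y.shape
        grand = float(Y.mean())
        line_means = Y.mean(axis=1)
        env_means = Y.mean(axis=0)
        ms_g = e * np.sum((line_means - grand) ** 2) / (n_l - 1)
        resid = Y - line_means[:, None] - env_means[None, :] + grand
        ms_ge = np.sum(resid**2) / ((n_l - 1) * (e - 1))
    sigma2_g = max((ms_g - ms_ge) / e, 0.0)
    return float(sigma2_g), float(ms_ge), int(e), grand


def broad_sense_heritability(table: pd.DataFrame, trait: str) -> float:
    """Entry-mean broad-sense heritability (percent) across environments."""
    _validate_table(table)
    sub = table[(table["trait"] == trait) & (table["environment"] != COMBINED)]
    if sub["line"].nunique() < 20:
        warnings.warn("fewer than 20 lines: heritability estimate is unstable")
    sigma2_g, ms_ge, e, _ = variance_components(table, trait)
    denom = sigma2_g + ms_ge / e
    if denom == 0:
        return 100.0 if sigma2_g > 0 else float("nan")
    return float(np.clip(100.0 * sigma2_g / denom, 0.0, 100.0))


def trait_summary(table: pd.DataFrame, trait: str, environment: str | None = None) -> TraitSummary:
    """Mean, range and variation statistics for one trait.

    With ``environment`` given the slice's GCV falls back to the phenotypic CV
    and h2 is undefined; with ``environment=None`` and >= 2 environments the
    genotypic components are used.
    """
    _validate_table(table)
    sub = table[table["trait"] == trait]
    if environment is not None:
        sub = sub[sub["environment"] == environment]
    if sub["line"].nunique() < 2:
        raise ValueError("trait summary requires at least two lines with data")
    values = sub["value"].to_numpy()
    mean = float(values.mean())
    if abs(mean) < 1e-12:
        raise ValueError("GCV undefined for zero trait mean")
    if environment is not None:
        gcv = 100.0 * float(values.std(ddof=1)) / abs(mean)
        h2 = float("nan")
    else:
        sigma2_g, _, _, grand = variance_components(table, trait)
        gcv = 100.0 * float(np.sqrt(sigma2_g)) / abs(grand)
        h2 = broad_sense_heritability(table, trait)
    return TraitSummary(
        trait=trait,
        environment=environment,
        n_lines=int(sub["line"].nunique()),
        mean=mean,
        minimum=float(values.min()),
        maximum=float(values.max()),
        gcv=gcv,
        h2=h2,
    )


def trait_table(
    table: pd.DataFrame,
    parents: pd.DataFrame | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive-statistics report: one row per trait and environment
    (individual environments then combined), values half-up rounded to 2 dp."""
    table = combine_environments(table)
    if parents is not None and len(parents):
        parents = combine_environments(parents)
    traits = traits or sorted(table["trait"].unique())
    rows = []
    for trait in traits:
        envs = [e for e in table.loc[table["trait"] == trait, "environment"].unique() if e != COMBINED]
        for env in sorted(envs) + [COMBINED]:
            s = trait_summary(table, trait, env)
            multi = trait_summary(table, trait, None) if env == COMBINED and len(envs) >= 2 else None
            row = {
                "trait": trait,
                "environment": env,
                "mean": round_half_up(s.mean),
                "min": round_half_up(s.minimum),
                "max": round_half_up(s.maximum),
                "cv_pct": round_half_up(s.gcv),
                "gcv_pct": round_half_up(multi.gcv) if multi else np.nan,
                "h2_pct": round_half_up(multi.h2) if multi else np.nan,
            }
            if parents is not None and len(parents):
                psub = parents[(parents["trait"] == trait) & (parents["environment"] == env)]
                for i, pline in enumerate(sorted(parents["line"].unique())[:2], start=1):
                    v = psub.loc[psub["line"] == pline, "value"]
                    row[f"P{i}"] = round_half_up(float(v.iloc[0])) if len(v) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
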