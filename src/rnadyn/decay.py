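"""mRNA decay kinetics from qPCR Ct tables.

Relative expression follows the ddCt method: per replicate,
``dCt = Ct(target) - Ct(control)``; referenced to the mean dCt of a
calibrator sample (by default the earliest timepoint of each group, so
every group's decay curve starts at 1), expression is ``2**(-ddCt)``.
Replicate outliers are removed by a median absolute deviation rule.
Half-lives come from a nonlinear least-squares fit of
``A * exp(-k t)`` to replicate-level points, ``t_half = ln 2 / k``.
Group comparisons use classical one-way and two-way (with replication)
ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "DecayCurve",
    "DecayFit",
    "DecayModel",
    "DecayResults",
    "relative_expression",
    "fit_halflife",
    "anova_oneway",
    "anova_twoway",
]

QPCR_COLUMNS = ("sample_group", "timepoint_min", "replicate_id", "ct_target", "ct_control")


@dataclass
class DecayCurve:
    """Relative expression vs time for one sample group."""

    group: str
    data: pd.DataFrame  # timepoint_min, replicate, value (outliers removed)
    n_outliers_removed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.data["value"] <= 0):
            raise ValueError("relative expression values must be > 0")


@dataclass
class DecayFit:
    k_per_min: float
    half_life_min: float
    amplitude: float
    r_squared: float
    n_points: int
    se_half_life_min: float | None = None  # across runs, when supplied


def _validate_qpcr(records: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records).copy()
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    for col in ("ct_target", "ct_control"):
        if np.any((df[col] <= 0) | (df[col] >= 45)):
            raise ValueError(f"{col} values must lie in (0, 45) cycles")
    return df


def relative_expression(
    records: pd.DataFrame,
    reference: tuple[str, float] | None = None,
    *,
    outlier_mad_factor: float | None = 3.0,
) -> dict[str, DecayCurve]:
    """ddCt relative expression per group.

    ``reference`` names a (group, timepoint) calibrator applied to all
    groups; by default each group is referenced to its own earliest
    timepoint.  After the ddCt transform, replicates farther than
    ``outlier_mad_factor`` times the MAD from their (group, timepoint)
    median are removed and counted (``None`` disables removal).
    """
    df = _validate_qpcr(records)
    df["dct"] = df["ct_target"] - df["ct_control"]
    curves: dict[str, DecayCurve] = {}
    for group, grp in df.groupby("sample_group", sort=True):
        if reference is None:
            ref_group, ref_time = group, grp["timepoint_min"].min()
        else:
            ref_group, ref_time = reference
        ref_rows = df[
            (df["sample_group"] == ref_group) & (df["timepoint_min"] == ref_time)
        ]
        if len(ref_rows) == 0:
            raise ValueError(f"reference sample ({ref_group}, {ref_time}) not found")
        ref_dct = float(ref_rows["dct"].mean())
        out = grp.copy()
        out["ddct"] = out["dct"] - ref_dct
        out["value"] = 2.0 ** (-out["ddct"])
        removed = 0
        if outlier_mad_factor is not None:
            keep_idx = []
            for _, cell in out.groupby("timepoint_min"):
                v = cell["value"]
                med = v.median()
                mad = (v - med).abs().median()
                if mad > 0:
                    ok = (v - med).abs() <= outlier_mad_factor * mad
                else:
                    ok = pd.Series(True, index=v.index)
                keep_idx.extend(v.index[ok])
                removed += int((~ok).sum())
            out = out.loc[sorted(keep_idx)]
        curves[str(group)] = DecayCurve(
            group=str(group),
            data=out[["timepoint_min", "replicate_id", "value"]]
            .rename(columns={"replicate_id": "replicate"})
            .reset_index(drop=True),
            n_outliers_removed=removed,
        )
    return curves


class DecayModel:
    """Single-exponential decay model ``A * exp(-k t)`` for one curve.

    Fitted to replicate-level points (not timepoint means), so triplicate
    scatter weights the fit where the data are."""

    def __init__(self, curve: DecayCurve | pd.DataFrame):
        if isinstance(curve, DecayCurve):
            data = curve.data
            self.group = curve.group
        else:
            data = pd.DataFrame(curve)
            self.group = "unnamed"
        if data["timepoint_min"].nunique() < 3:
            raise ValueError("need at least 3 timepoints for a decay fit")
        self.t = data["timepoint_min"].to_numpy(dtype=float)
        self.y = data["value"].to_numpy(dtype=float)

    def fit(self) -> "DecayResults":
        t, y = self.t, self.y
        # log-linear initialisation
        k0 = max(1e-6, -np.polyfit(t, np.log(np.clip(y, 1e-12, None)), 1)[0])
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, a, k: a * np.exp(-k * tt),
                t,
                y,
                p0=(float(y.max()), k0),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"decay fit did not converge: {exc}") from exc
        a_hat, k_hat = float(popt[0]), float(popt[1])
        span = t.max() - t.min()
        if k_hat <= 0 or k_hat * span < 1e-6:
            raise RuntimeError(
                "decay rate not identifiable (curve is flat over the sampled times)"
            )
        resid = y - a_hat * np.exp(-k_hat * t)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fit = DecayFit(
            k_per_min=k_hat,
            half_life_min=math.log(2.0) / k_hat,
            amplitude=a_hat,
            r_squared=r2,
            n_points=len(t),
        )
        return DecayResults(fit=fit, group=self.group, t=t, y=y)


@dataclass
class DecayResults:
    fit: DecayFit
    group: str
    t: np.ndarray
    y: np.ndarray

    @property
    def half_life_min(self) -> float:
        return self.fit.half_life_min

    def summary(self) -> str:
        f = self.fit
        return "\n".join(
            [
                f"Single-exponential decay fit [{self.group}]",
                f"  half-life: {f.half_life_min:.2f} min",
                f"  rate k:    {f.k_per_min:.4f} /min",
                f"  amplitude: {f.amplitude:.3f}",
                f"  R^2:       {f.r_squared:.4f}  ({f.n_points} replicate points)",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.y, "o", label="replicates")
        tt = np.linspace(0, float(self.t.max()), 200)
        ax.plot(tt, self.fit.amplitude * np.exp(-self.fit.k_per_min * tt), "-",
                label=f"t1/2 = {self.half_life_min:.1f} min")
        ax.set_xlabel("time after transcription block (min)")
        ax.set_ylabel("relative expression")
        ax.legend()
        return ax


def fit_halflife(curve: DecayCurve | pd.DataFrame | list) -> DecayFit:
    """Half-life from a single-exponential fit.

    Accepts one curve, or a list of curves (independent runs), in which
    case the mean half-life is reported with the across-run standard
    deviation in ``se_half_life_min``.
    """
    if isinstance(curve, list):
        fits = [DecayModel(c).fit().fit for c in curve]
        halves = np.array([f.half_life_min for f in fits])
        mean_fit = fits[0]
        return DecayFit(
            k_per_min=math.log(2.0) / float(halves.mean()),
            half_life_min=float(halves.mean()),
            amplitude=float(np.mean([f.amplitude for f in fits])),
            r_squared=float(np.mean([f.r_squared for f in fits])),
            n_points=int(sum(f.n_points for f in fits)),
            se_half_life_min=float(halves.std(ddof=1)) if len(halves) > 1 else None,
        )
    return DecayModel(curve).fit().fit


def anova_oneway(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Classical one-way ANOVA; returns an effect table with F and p."""
    from scipy import stats

    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    f, p = stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    return pd.DataFrame(
        [
            {
                "effect": "group",
                "df": len(groups) - 1,
                "df_resid": n - len(groups),
                "F": float(f),
                "p": float(p),
            }
        ]
    )


def anova_twoway(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "sample_group",
    factor_b: str = "timepoint_min",
) -> pd.DataFrame:
    """Two-way ANOVA with replication, including the interaction.

    Requires balanced replication (equal cell counts); unbalanced input
    raises with a pointer to per-timepoint one-way tests, whose
    interpretation does not depend on the ANOVA decomposition.
    """
    df = pd.DataFrame(data).copy()
    cells = df.groupby([factor_a, factor_b]).size()
    n_a = df[factor_a].nunique()
    n_b = df[factor_b].nunique()
    if len(cells) != n_a * n_b or cells.nunique() != 1:
        raise ValueError(
            "two-way ANOVA with replication requires balanced cells; "
            "run one-way ANOVA per timepoint instead"
        )
    if cells.iloc[0] < 2:
        raise ValueError("two-way ANOVA with replication needs >= 2 replicates per cell")
    df = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    names = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    for idx, row in table.iterrows():
        if idx == "Residual":
            continue
        out.append(
            {
                "effect": names.get(idx, str(idx)),
                "df": int(row["df"]),
                "df_resid": int(table.loc["Residual", "df"]),
                "F": float(row["F"]),
                "p": float(row["PR(>F)"]),
            }
        )
    return pd.DataFrame(out)
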