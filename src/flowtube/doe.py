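"""Two-level factorial design generation and screening analysis.

The screening study varies five factors of the flow reactor — tubing length
(A), inner diameter (B), flow rate (C), bath temperature (D) and molar feed
ratio (E) — each at two levels, either as the full 2^5 design (32 runs) or
as the resolution-V half fraction 2^(5-1) with generator E = ABCD
(16 runs), in which two-factor interactions are aliased only with
three-factor ones.

Analysis follows standard unreplicated-factorial practice: effects are
estimated from orthogonal contrasts, ranked on a half-normal plot, and
screened with Lenth's pseudo-standard-error method; a coded-unit least
squares model of log10(% yield) with ANOVA (including PRESS-based predicted
R^2 and, for replicated data, pure error and lack of fit) quantifies the
retained terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FACTOR_LETTERS",
    "FACTOR_NAMES",
    "NATURAL_COLUMNS",
    "DesignError",
    "DesignSpec",
    "build_design",
    "estimate_effects",
    "lenth_screen",
    "LenthResult",
    "RegressionModel",
    "AnovaSummary",
    "FactorialModel",
    "FactorialResults",
    "fit_model",
    "predict_surface",
    "two_way_terms",
]

#: Letter codes A..E in the fixed factor order.
FACTOR_LETTERS = ("A", "B", "C", "D", "E")
#: Physical factor behind each letter.
FACTOR_NAMES = {"A": "L", "B": "ID", "C": "Q", "D": "T", "E": "chi"}
#: Natural-unit column name per factor.
NATURAL_COLUMNS = {
    "L": "L_m",
    "ID": "ID_mm",
    "Q": "Q_mL_min",
    "T": "T_C",
    "chi": "chi",
}

#: Default factor ranges (low, high) of the screening design.
DEFAULT_FACTOR_LEVELS: Mapping[str, tuple[float, float]] = {
    "L": (1.0, 5.0),
    "ID": (0.25, 1.0),
    "Q": (0.1, 1.0),
    "T": (10.0, 40.0),
    "chi": (0.95, 1.5),
}


class DesignError(ValueError):
    """Invalid or rank-deficient design specification."""


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a two-level screening design."""

    factors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LEVELS)
    )
    design_kind: str = "full_2k"  # or "fractional_2k_minus_1"
    generator: str = "E=ABCD"
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.design_kind not in ("full_2k", "fractional_2k_minus_1"):
            raise DesignError(f"unknown design kind {self.design_kind!r}")
        if set(self.factors) != set(FACTOR_NAMES.values()):
            raise DesignError(
                f"factors must be exactly {sorted(FACTOR_NAMES.values())}"
            )
        for name, (lo, hi) in self.factors.items():
            if not lo < hi:
                raise DesignError(f"factor {name}: low must be < high")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        if (
            self.design_kind == "fractional_2k_minus_1"
            and self.generator.replace(" ", "") != "E=ABCD"
        ):
            raise DesignError(
                "only the resolution-V generator E=ABCD is supported"
            )


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Coded and natural-unit run table for a design specification.

    Full designs enumerate all 32 sign combinations once; the half fraction
    takes the 16 runs of the 2^4 base design in A..D and sets E = ABCD.
    Replicates, if requested, repeat each run with a ``replicate`` index.
    """
    if spec.design_kind == "full_2k":
        rows = list(itertools.product((-1, 1), repeat=5))
    else:
        rows = [
            (a, b, c, d, a * b * c * d)
            for a, b, c, d in itertools.product((-1, 1), repeat=4)
        ]
    df = pd.DataFrame(rows, columns=list(FACTOR_LETTERS), dtype=float)
    for letter in FACTOR_LETTERS:
        name = FACTOR_NAMES[letter]
        lo, hi = spec.factors[name]
        centre, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        df[NATURAL_COLUMNS[name]] = centre + half * df[letter]
    df.insert(0, "run", np.arange(1, len(df) + 1))
    if spec.replicates > 1:
        df = df.loc[df.index.repeat(spec.replicates)].reset_index(drop=True)
        df["replicate"] = np.tile(
            np.arange(1, spec.replicates + 1), len(df) // spec.replicates
        )
    return df


def two_way_terms() -> list[str]:
    """Main effects plus all two-factor interaction terms, e.g. 'BD'."""
    mains = list(FACTOR_LETTERS)
    inters = [
        "".join(p) for p in itertools.combinations(FACTOR_LETTERS, 2)
    ]
    return mains + inters


def _contrast_matrix(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for term in terms:
        col = np.ones(len(design))
        for letter in term:
            if letter not in FACTOR_LETTERS:
                raise DesignError(f"unknown factor letter in term {term!r}")
            col = col * design[letter].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def estimate_effects(
    design: pd.DataFrame,
    response: Sequence[float],
    terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Contrast-based effect estimates with half-normal plotting positions.

    The effect of a term is the mean response at its +1 contrast level minus
    the mean at -1; the regression coefficient is half the effect.  Rows are
    ordered by |effect| with half-normal quantiles assigned by rank.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(design):
        raise ValueError("response length must match the design")
    terms = list(terms) if terms is not None else two_way_terms()
    X = _contrast_matrix(design, terms)
    effects = 2.0 * (X.T @ y) / len(y)
    table = pd.DataFrame(
        {
            "term": terms,
            "effect": effects,
            "coefficient": effects / 2.0,
            "sign": np.sign(effects),
        }
    )
    table = table.reindex(
        table["effect"].abs().sort_values().index
    ).reset_index(drop=True)
    m = len(table)
    ranks = np.arange(1, m + 1)
    table["rank"] = ranks
    table["half_normal_quantile"] = stats.norm.ppf(
        0.5 + 0.5 * (ranks - 0.5) / m
    )
    table["significant"] = False
    return table


@dataclass(frozen=True)
class LenthResult:
    """Lenth pseudo-standard-error screening summary."""

    s0: float
    pse: float
    margin: float
    sme_margin: float
    alpha: float
    significant: tuple[str, ...]
    significant_sme: tuple[str, ...]


def lenth_screen(
    effects: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, LenthResult]:
    """Flag active effects with Lenth's pseudo-standard-error method.

    s0 = 1.5 * median|effect|; the pseudo standard error re-medians the
    effects smaller than 2.5 s0; the margin of error is t(1-alpha/2, m/3)
    times the PSE, with m the number of effects considered.  The per-effect
    margin controls each contrast's error rate; the simultaneous margin
    (SME, reported alongside) controls the family-wise rate and is the
    appropriate yardstick when asking whether the flagged *set* is exactly
    the active one.
    """
    if len(effects) < 7:
        raise ValueError("Lenth screening needs at least 7 effects")
    e = effects["effect"].to_numpy(dtype=float)
    abs_e = np.abs(e)
    m = len(e)
    s0 = 1.5 * float(np.median(abs_e))
    if s0 == 0.0:
        flagged = flagged_sme = np.zeros(m, dtype=bool)
        result = LenthResult(0.0, 0.0, 0.0, 0.0, alpha, (), ())
    else:
        trimmed = abs_e[abs_e < 2.5 * s0]
        pse = 1.5 * float(np.median(trimmed)) if trimmed.size else s0
        dof = m / 3.0
        margin = float(stats.t.ppf(1.0 - alpha / 2.0, dof)) * pse
        gamma = 0.5 * (1.0 + (1.0 - alpha) ** (1.0 / m))
        sme = float(stats.t.ppf(gamma, dof)) * pse
        flagged = abs_e > margin
        flagged_sme = abs_e > sme
        result = LenthResult(
            s0,
            pse,
            margin,
            sme,
            alpha,
            tuple(effects.loc[flagged, "term"]),
            tuple(effects.loc[flagged_sme, "term"]),
        )
    out = effects.copy()
    out["significant"] = flagged
    out["significant_sme"] = flagged_sme
    return out, result


@dataclass(frozen=True)
class RegressionModel:
    """Coded-unit regression of (transformed) percent yield."""

    intercept: float
    coefficients: Mapping[str, float]  # term -> coded-unit coefficient
    transform: str = "log10"  # "log10" or "identity"
    floor: float = 0.01  # % yield floor applied before the log transform
    hierarchy_terms: tuple[str, ...] = ()

    def predict_transformed(self, coded: pd.DataFrame) -> np.ndarray:
        """Model prediction on the transformed (log10) scale."""
        pred = np.full(len(coded), self.intercept, dtype=float)
        for term, coef in self.coefficients.items():
            col = np.ones(len(coded))
            for letter in term:
                col = col * coded[letter].to_numpy(dtype=float)
            pred += coef * col
        return pred

    def predict_percent(self, coded: pd.DataFrame) -> np.ndarray:
        """Prediction in % yield (inverse transform applied)."""
        pred = self.predict_transformed(coded)
        if self.transform == "log10":
            return 10.0**pred
        return pred


@dataclass(frozen=True)
class AnovaSummary:
    """ANOVA of a coded factorial regression."""

    f_model: float
    p_model: float
    term_p: Mapping[str, float]
    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    press: float
    residual_ms: float
    pure_error_ms: float | None = None
    lack_of_fit_f: float | None = None
    lack_of_fit_p: float | None = None

    def __post_init__(self) -> None:
        if self.r_squared < self.adj_r_squared - 1e-12:
            raise ValueError("R^2 must be >= adjusted R^2")


class FactorialModel:
    """Least-squares factorial model of percent yield in coded units.

    Parameters
    ----------
    design : DataFrame
        Run table with coded columns A..E (one row per observation; for
        replicated campaigns repeat the rows).
    response : sequence of float
        Percent yield per observation (strictly positive after flooring).
    terms : sequence of str, optional
        Retained terms, e.g. ``["A", "B", "C", "D"]``; parents of retained
        interactions are added automatically to maintain hierarchy.
    transform : {"log10", "identity"}
        Response transform; the screening response is log10(% yield) with a
        0.01% floor guarding degenerate zero-yield runs.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        response: Sequence[float],
        terms: Sequence[str] | None = None,
        transform: str = "log10",
        floor: float = 0.01,
    ):
        self.design = design.reset_index(drop=True)
        y = np.asarray(response, dtype=float)
        if len(y) != len(self.design):
            raise ValueError("response length must match the design")
        if transform not in ("log10", "identity"):
            raise ValueError("transform must be 'log10' or 'identity'")
        if transform == "log10":
            if np.any(y <= 0.0) and floor <= 0.0:
                raise ValueError(
                    "non-positive yields require a positive floor "
                    "before the log transform"
                )
            y = np.log10(np.maximum(y, floor))
        self.y = y
        self.transform = transform
        self.floor = floor
        requested = list(terms) if terms is not None else list(FACTOR_LETTERS)
        hierarchy = []
        for term in requested:
            for letter in term:
                if letter not in requested and letter not in hierarchy:
                    hierarchy.append(letter)
        self.terms = hierarchy + requested
        self.hierarchy_terms = tuple(hierarchy)

    def fit(self) -> "FactorialResults":
        X = _contrast_matrix(self.design, self.terms)
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            aliased = []
            corr = np.corrcoef(X, rowvar=False)
            for i in range(len(self.terms)):
                for j in range(i + 1, len(self.terms)):
                    if abs(corr[i, j]) > 1.0 - 1e-9:
                        aliased.append(f"{self.terms[i]}={self.terms[j]}")
            raise DesignError(
                "rank-deficient design; aliased terms: "
                + (", ".join(aliased) or "unidentified")
            )
        ols = sm.OLS(self.y, Xc).fit()
        return FactorialResults(self, ols)


class FactorialResults:
    """Fitted factorial model: coefficients, ANOVA and predictions."""

    def __init__(self, model: FactorialModel, ols):
        self.model = model
        self._ols = ols
        params = np.asarray(ols.params)
        self.intercept = float(params[0])
        self.coefficients = dict(zip(model.terms, params[1:]))
        self.regression = RegressionModel(
            intercept=self.intercept,
            coefficients=self.coefficients,
            transform=model.transform,
            floor=model.floor,
            hierarchy_terms=model.hierarchy_terms,
        )
        self.anova = self._build_anova()

    def _build_anova(self) -> AnovaSummary:
        ols = self._ols
        model = self.model
        y = model.y
        n = len(y)
        influence = ols.get_influence()
        press = float(np.sum(influence.resid_press**2))
        ss_total = float(np.sum((y - y.mean()) ** 2))
        pred_r2 = 1.0 - press / ss_total if ss_total > 0 else np.nan

        pure_ms = lof_f = lof_p = None
        key = list(map(tuple, model.design[list(FACTOR_LETTERS)].to_numpy()))
        groups = pd.Series(np.arange(n)).groupby(pd.Series(key, dtype="object"))
        sizes = groups.size()
        if (sizes > 1).any():
            ss_pe, df_pe = 0.0, 0
            for _, idx in groups.groups.items():
                vals = y[list(idx)]
                ss_pe += float(np.sum((vals - vals.mean()) ** 2))
                df_pe += len(vals) - 1
            n_cond = len(sizes)
            p_full = int(ols.df_model) + 1
            df_lof = n_cond - p_full
            sse = float(np.sum(ols.resid**2))
            ss_lof = max(sse - ss_pe, 0.0)
            pure_ms = ss_pe / df_pe if df_pe > 0 else 0.0
            if df_lof > 0 and df_pe > 0 and pure_ms > 0:
                lof_f = (ss_lof / df_lof) / pure_ms
                lof_p = float(stats.f.sf(lof_f, df_lof, df_pe))

        term_p = dict(zip(model.terms, np.asarray(ols.pvalues)[1:]))
        return AnovaSummary(
            f_model=float(ols.fvalue),
            p_model=float(ols.f_pvalue),
            term_p=term_p,
            r_squared=float(ols.rsquared),
            adj_r_squared=float(ols.rsquared_adj),
            pred_r_squared=float(pred_r2),
            press=press,
            residual_ms=float(ols.mse_resid),
            pure_error_ms=pure_ms,
            lack_of_fit_f=lof_f,
            lack_of_fit_p=lof_p,
        )

    def predict_percent(self, coded: pd.DataFrame) -> np.ndarray:
        return self.regression.predict_percent(coded)

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        """Terms with per-term F-test p-values below alpha."""
        return [t for t, p in self.anova.term_p.items() if p < alpha]

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Coded-unit factorial model "
            f"({self.model.transform} response, n={len(self.model.y)})",
            f"  intercept            {self.intercept:+.4f}",
        ]
        for term in self.model.terms:
            lines.append(
                f"  {term:<4} coefficient    {self.coefficients[term]:+.4f}"
                f"   p={a.term_p[term]:.3g}"
            )
        lines += [
            f"  model F = {a.f_model:.4g} (p = {a.p_model:.3g})",
            f"  R^2 = {a.r_squared:.4f}  adj = {a.adj_r_squared:.4f}"
            f"  pred = {a.pred_r_squared:.4f}",
        ]
        if a.pure_error_ms is not None:
            lines.append(f"  pure error MS = {a.pure_error_ms:.4g}")
        if a.lack_of_fit_f is not None:
            lines.append(
                f"  lack-of-fit F = {a.lack_of_fit_f:.3g}"
                f" (p = {a.lack_of_fit_p:.3g})"
            )
        return "\n".join(lines)


def fit_model(
    design: pd.DataFrame,
    response: Sequence[float],
    retained_terms: Sequence[str] | None = None,
    transform: str = "log10",
) -> tuple[RegressionModel, AnovaSummary]:
    """Functional wrapper: fit and return (RegressionModel, AnovaSummary)."""
    res = FactorialModel(design, response, retained_terms, transform).fit()
    return res.regression, res.anova


def predict_surface(
    model: RegressionModel,
    factor_x: str,
    factor_y: str,
    n: int = 21,
    limits: tuple[float, float] = (-1.0, 1.0),
) -> pd.DataFrame:
    """Percent-yield surface over two coded factors, others at the centre.

    Returns a long-format frame with columns (factor_x, factor_y,
    yield_pct).  Requesting values beyond +-1 logs a warning (extrapolation
    outside the design region).
    """
    if factor_x not in FACTOR_LETTERS or factor_y not in FACTOR_LETTERS:
        raise ValueError("factors must be letters A..E")
    lo, hi = limits
    if lo < -1.0 or hi > 1.0:
        warnings.warn("surface extends beyond the coded design region")
    xs = np.linspace(lo, hi, n)
    grid = pd.DataFrame(
        [(x, yv) for x in xs for yv in xs], columns=[factor_x, factor_y]
    )
    coded = pd.DataFrame(0.0, index=grid.index, columns=list(FACTOR_LETTERS))
    coded[factor_x] = grid[factor_x]
    coded[factor_y] = grid[factor_y]
    grid["yield_pct"] = model.predict_percent(coded)
    return grid
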