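"""ERP component quantification and mixed-model likelihood-ratio tests.

Each component is the mean voltage in a fixed window at a fixed channel
(parietal shift 250–700 ms at Pz; P200 100–250 ms at Fz; P300 250–350,
N400 350–500, P600 500–800 ms at Pz).  Per-epoch component means are
joined with word covariates, standardized, and modelled with linear mixed
models: fixed effects for information gain, word length, log-frequency,
word class and document preference; crossed random intercepts for subjects
and word types (fit by maximum likelihood so model comparisons are valid).
The information-gain effect is tested by a 1-df likelihood-ratio test of
the full model against the same model without the gain term, Bonferroni
corrected over the four component models where applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .epochs import EpochArray

__all__ = [
    "ComponentSpec",
    "DEFAULT_COMPONENTS",
    "FIXED_EFFECTS",
    "component_means",
    "standardize",
    "fit_mixed",
    "simplify_random_effects",
    "lrt_information_gain",
    "r_squared",
]


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    window_ms: tuple[float, float]
    channel: str


DEFAULT_COMPONENTS: list[ComponentSpec] = [
    ComponentSpec("EPS", (250.0, 700.0), "Pz"),
    ComponentSpec("P200", (100.0, 250.0), "Fz"),
    ComponentSpec("P300", (250.0, 350.0), "Pz"),
    ComponentSpec("N400", (350.0, 500.0), "Pz"),
    ComponentSpec("P600", (500.0, 800.0), "Pz"),
]

FIXED_EFFECTS = ["information_gain", "length", "log_frequency", "word_class", "preference"]

#: maximal random structure attempted before simplification
MAXIMAL_RANDOM_TERMS = ["ig_by_subject", "subject", "word"]

_VC_FORMULAS = {
    "subject": "0 + C(subject)",
    "word": "0 + C(word)",
    "ig_by_subject": "0 + C(subject):information_gain",
}


def component_means(
    epochs: EpochArray,
    specs: list[ComponentSpec] | None = None,
    stats: pd.DataFrame | None = None,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Per-epoch mean voltage of every component, joined with covariates.

    Windows are closed intervals on the epoch time axis.  Word-level
    covariates (length, log-frequency, word class) are joined from *stats*
    when given; rejected epochs are excluded when a QC mask is present.
    """
    specs = specs or DEFAULT_COMPONENTS
    if retained_only:
        epochs = epochs.retained()
    table = epochs.metadata.copy().reset_index(drop=True)
    for spec in specs:
        if spec.window_ms[0] < epochs.times[0] or spec.window_ms[1] > epochs.times[-1]:
            raise ValueError(
                f"component {spec.name} window {spec.window_ms} outside epoch span "
                f"[{epochs.times[0]}, {epochs.times[-1]}] ms"
            )
        tmask = epochs.time_mask(*spec.window_ms)
        table[spec.name] = epochs.data[:, epochs.ch_index(spec.channel), :][:, tmask].mean(axis=1)
    if stats is not None:
        cols = [c for c in ("length", "log_frequency", "word_class") if c in stats.columns]
        table = table.merge(stats[["word"] + cols], on="word", how="left", validate="m:1")
    return table


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Z-score continuous columns; code binary covariates 0/1.

    ``word_class`` is mapped functional→1, content→0; ``preference`` is
    already 0/1 and left as is.  A zero-variance continuous column is an
    error naming the column.
    """
    out = table.copy()
    if "word_class" in out.columns and out["word_class"].dtype == object:
        out["word_class"] = (out["word_class"] == "functional").astype(float)
    if columns is None:
        columns = [c for c in out.columns
                   if c in {s.name for s in DEFAULT_COMPONENTS}
                   or c in ("information_gain", "length", "log_frequency")]
    for col in columns:
        v = out[col].to_numpy(float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (v - v.mean()) / sd
    return out


@dataclass
class MixedFit:
    """A fitted mixed model plus the pieces the pipeline consumes."""

    dependent: str
    fixed: list[str]
    random_terms: list[str]
    loglik: float
    converged: bool
    fe_params: pd.Series
    vcomp: dict[str, float]
    scale: float
    fitted_fixed: np.ndarray = field(repr=False)
    result: object = field(repr=False, default=None)


def fit_mixed(
    table: pd.DataFrame,
    dependent: str,
    fixed: list[str] | None = None,
    random_terms: list[str] | None = None,
) -> MixedFit:
    """ML fit of ``dependent ~ fixed`` with the requested random terms.

    Crossed subject/word intercepts (and optionally a by-subject gain
    slope) are expressed as variance components over a single grouping
    level.  Non-convergence is reported in the ``converged`` flag, never
    raised.
    """
    fixed = list(FIXED_EFFECTS if fixed is None else fixed)
    random_terms = list(MAXIMAL_RANDOM_TERMS if random_terms is None else random_terms)
    if table["subject"].nunique() < 2 or table["word"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects and 2 words")
    df = table.copy()
    df["_one"] = 1
    rhs = " + ".join(fixed) if fixed else "1"
    vc = {t: _VC_FORMULAS[t] for t in random_terms}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"{dependent} ~ {rhs}", groups="_one", vc_formula=vc, re_formula="0", data=df
        )
        # single quasi-Newton runs occasionally stall short of the optimum,
        # which corrupts likelihood-ratio statistics; accept a cleanly
        # converged quasi-Newton fit, otherwise fall back to derivative-free
        # optimizers and keep the best likelihood
        candidates = []
        for method in ("bfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=300)
                if np.isfinite(cand.llf):
                    candidates.append(cand)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if candidates and any(c.converged for c in candidates):
                break
    if candidates:
        res = max(candidates, key=lambda c: c.llf)
        agree = len(candidates) > 1 and abs(candidates[0].llf - candidates[1].llf) < 1e-2
        converged = (bool(res.converged) or agree) and np.isfinite(res.llf)
    else:
        res = None
    if res is None:
        return MixedFit(dependent, fixed, random_terms, -np.inf, False,
                        pd.Series(dtype=float), {t: np.nan for t in random_terms},
                        np.nan, np.zeros(len(df)))
    vcomp = dict(zip(random_terms, np.asarray(res.vcomp, float)))
    fitted_fixed = np.asarray(model.exog @ res.fe_params)
    return MixedFit(dependent, fixed, random_terms, float(res.llf), converged,
                    res.fe_params, vcomp, float(res.scale), fitted_fixed, res)


def simplify_random_effects(
    table: pd.DataFrame,
    dependent: str,
    fixed: list[str] | None = None,
    random_terms: list[str] | None = None,
) -> tuple[MixedFit, list[str]]:
    """Fit the maximal random structure, dropping the smallest-variance term
    until the fit converges.

    Returns the converged fit and the trail of removed terms.  Raises if
    even intercept-only structures fail.
    """
    terms = list(MAXIMAL_RANDOM_TERMS if random_terms is None else random_terms)
    trail: list[str] = []
    while True:
        fit = fit_mixed(table, dependent, fixed, terms)
        if fit.converged:
            return fit, trail
        if len(terms) <= 1:
            raise RuntimeError(
                f"no converging random-effects structure for {dependent}; trail={trail}"
            )
        variances = {t: fit.vcomp.get(t, np.nan) for t in terms}
        # drop the term explaining the least variance (NaNs count as least)
        drop = min(variances, key=lambda t: (not np.isnan(variances[t]), variances[t]))
        terms = [t for t in terms if t != drop]
        trail.append(drop)


@dataclass
class ModelComparison:
    component: str
    chi_square: float
    df: int
    p_raw: float
    p_bonferroni: float
    slopes: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    random_terms: list[str]
    removal_trail: list[str]

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "effect": "information_gain",
            "chi2": self.chi_square,
            "df": self.df,
            "p": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "slope": self.slopes.get("information_gain", float("nan")),
            "slopes": self.slopes,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "random_terms": self.random_terms,
            "removal_trail": self.removal_trail,
        }


def r_squared(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R² by fixed/random variance decomposition.

    marginal = var(Xβ) / (var(Xβ) + Σ random variances + residual);
    conditional adds the random variances to the numerator.
    """
    if not fit.converged:
        raise ValueError("R² requires a converged fit")
    var_fixed = float(np.var(fit.fitted_fixed))
    var_random = float(sum(v for v in fit.vcomp.values() if np.isfinite(v)))
    total = var_fixed + var_random + fit.scale
    return var_fixed / total, (var_fixed + var_random) / total


def lrt_information_gain(
    table: pd.DataFrame,
    dependent: str = "EPS",
    m_correction: int = 1,
    fixed: list[str] | None = None,
    random_terms: list[str] | None = None,
) -> ModelComparison:
    """Likelihood-ratio test of the information-gain fixed effect.

    The full model's random structure is simplified to convergence and
    reused for the reduced model so the pair differs only in the gain term.
    """
    fixed = list(FIXED_EFFECTS if fixed is None else fixed)
    if "information_gain" not in fixed:
        raise ValueError("fixed effects must include information_gain")
    if table["information_gain"].nunique() == 1:
        # a constant covariate carries no information and would make the
        # full design singular: the two models coincide exactly
        reduced_fixed = [f for f in fixed if f != "information_gain"]
        reduced, trail = simplify_random_effects(table, dependent, reduced_fixed, random_terms)
        r2m, r2c = r_squared(reduced)
        slopes = {k: float(v) for k, v in reduced.fe_params.items() if k != "Intercept"}
        slopes["information_gain"] = 0.0
        return ModelComparison(dependent, 0.0, 1, 1.0, 1.0, slopes, r2m, r2c,
                               reduced.random_terms, trail)
    full, trail = simplify_random_effects(table, dependent, fixed, random_terms)
    reduced_fixed = [f for f in fixed if f != "information_gain"]
    reduced = fit_mixed(table, dependent, reduced_fixed, full.random_terms)
    if not reduced.converged:
        reduced, _ = simplify_random_effects(table, dependent, reduced_fixed, full.random_terms)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p_raw = float(sps.chi2.sf(chi2, df=1))
    r2m, r2c = r_squared(full)
    slopes = {k: float(v) for k, v in full.fe_params.items() if k != "Intercept"}
    return ModelComparison(
        component=dependent,
        chi_square=chi2,
        df=1,
        p_raw=p_raw,
        p_bonferroni=min(1.0, m_correction * p_raw),
        slopes=slopes,
        r2_marginal=r2m,
        r2_conditional=r2c,
        random_terms=full.random_terms,
        removal_trail=trail,
    )
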