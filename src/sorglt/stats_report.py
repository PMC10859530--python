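"""Mixed-model inference on the factorial outputs, and report tables.

The response (grain yield, transpiration, water productivity, ...) is
modelled with fixed effects for trait (G_T), maturity group (G_M),
planting date (M_P) and water-stress environment (E_W) plus their
interactions, and random intercepts for location and for year nested in
location.  Model search is a backward-elimination stepwise on AIC that
respects marginality, the selected model is compared with the four-way
interaction model by a likelihood-ratio test, and factor-level
comparisons use Tukey's HSD on mixed-model estimated marginal means,
gated on the factor's F test at alpha = 0.05.

Fitting delegates to statsmodels MixedLM (ML for model comparison, REML
for final estimates).  Denominator degrees of freedom for F tests and
Tukey comparisons use a residual-dof approximation (n minus fixed-effect
rank), a simplification of the Satterthwaite machinery of lmerTest-style
workflows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf

# Factor symbols and the table columns they live in.
FACTORS = {"GT": "trait", "GM": "maturity", "MP": "planting", "EW": "env"}
Term = tuple[str, ...]  # sorted tuple of factor symbols, e.g. ("EW", "GT")


def _term(*symbols: str) -> Term:
    return tuple(sorted(symbols))


MAIN_TERMS = tuple(_term(s) for s in FACTORS)
FULL_TERMS = tuple(
    _term(*c)
    for r in range(1, 5)
    for c in itertools.combinations(FACTORS, r)
)

# The four published model presets (grain yield; biomass at flowering;
# transpiration at flowering; water productivity).
MODEL_PRESETS: dict[str, tuple[Term, ...]] = {
    "eq1": MAIN_TERMS + (
        _term("GT", "EW"), _term("GM", "MP"), _term("EW", "MP"),
        _term("GM", "EW"), _term("GM", "EW", "MP")),
    "eq2": MAIN_TERMS + (
        _term("GT", "GM"), _term("GT", "EW"), _term("GM", "MP"),
        _term("EW", "MP"), _term("GM", "EW"), _term("GM", "EW", "MP")),
    "eq3": MAIN_TERMS + (
        _term("GT", "GM"), _term("GT", "EW"), _term("EW", "MP"),
        _term("GM", "EW"), _term("GT", "EW", "MP")),
    "eq4": MAIN_TERMS + (
        _term("GT", "EW"), _term("GM", "MP"), _term("GM", "EW")),
    "full": FULL_TERMS,
}


@dataclass(frozen=True)
class ModelSpec:
    """Response plus the fixed-effect terms; the random part is fixed to
    intercepts for location and year-within-location."""

    response: str
    fixed_terms: tuple[Term, ...]
    location_col: str = "site"
    year_col: str = "year"

    def formula(self) -> str:
        if not self.fixed_terms:
            return f"{self.response} ~ 1"
        parts = [":".join(f"C({FACTORS[s]})" for s in t)
                 for t in self.fixed_terms]
        return f"{self.response} ~ " + " + ".join(parts)

    def drop(self, term: Term) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(
            t for t in self.fixed_terms if t != term))

    def removable_terms(self) -> list[Term]:
        """Terms not contained in any retained higher-order term."""
        out = []
        for t in self.fixed_terms:
            if not any(set(t) < set(o) for o in self.fixed_terms):
                out.append(t)
        return out


def spec(response: str, preset: str = "full") -> ModelSpec:
    return ModelSpec(response=response, fixed_terms=MODEL_PRESETS[preset])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    spec: ModelSpec
    result: object                  # statsmodels MixedLMResults
    reml: bool
    converged: bool
    llf: float
    n_params: int                   # fixed + variance parameters
    aic: float
    fe_params: pd.Series
    design_info: object = None      # patsy design of the *full* fixed part
    kept_columns: np.ndarray | None = None  # indices into the full design
    estimates: pd.Series = field(default_factory=pd.Series)
    levels: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return int(self.result.model.nobs)

    def resid_dof(self) -> int:
        return max(1, self.n_obs - len(self.fe_params))


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR).

    Unbalanced desk-scale tables can leave interaction cells empty, making
    treatment-coded designs rank deficient; aliased columns are dropped the
    way R's lm pivots them out.
    """
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0:
        return np.array([], dtype=int)
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def fit_mixed(model_spec: ModelSpec, table: pd.DataFrame,
              reml: bool = False) -> FitResult:
    """Fit the mixed model; ML by default (for AIC/LRT), REML on request.

    Random intercepts: one per location (grouping factor) and a variance
    component for year within location.  Aliased fixed-effect columns
    (empty design cells) are pivoted out before fitting.  Non-convergence
    is flagged on the result, never silently replaced.
    """
    data = table.dropna(subset=[model_spec.response]).copy()
    for col in FACTORS.values():
        if col not in data.columns:
            raise ValueError(f"table lacks factor column {col!r}")
    if data[model_spec.location_col].nunique() < 2:
        raise ValueError("need at least 2 locations for the random structure")

    ydf, Xdf = patsy.dmatrices(model_spec.formula(), data,
                               return_type="dataframe")
    data = data.loc[Xdf.index]
    keep = _independent_columns(np.asarray(Xdf))
    kept_names = [Xdf.columns[i] for i in keep]
    work = pd.DataFrame(np.asarray(Xdf)[:, keep],
                        columns=[f"_c{i}" for i in range(len(keep))],
                        index=Xdf.index)
    work["_y"] = np.asarray(ydf)[:, 0]
    work["_year"] = data[model_spec.year_col].to_numpy()
    rhs = " + ".join(work.columns[:len(keep)]) if len(keep) else "1"
    model = smf.mixedlm(
        f"_y ~ 0 + {rhs}", work,
        groups=data[model_spec.location_col],
        re_formula="1",
        vc_formula={"year": "0 + C(_year)"},
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=1000)
    converged = bool(getattr(res, "converged", True)) and np.isfinite(res.llf)
    n_params = (len(res.fe_params)
                + model.k_re * (model.k_re + 1) // 2
                + len(res.vcomp) + 1)
    fe = pd.Series(np.asarray(res.fe_params), index=kept_names)
    out = FitResult(
        spec=model_spec, result=res, reml=reml, converged=converged,
        llf=float(res.llf), n_params=n_params,
        aic=float(2 * n_params - 2 * res.llf),
        fe_params=fe, design_info=Xdf.design_info, kept_columns=keep,
        estimates=res.params,
    )
    out.levels = {col: sorted(data[col].astype(str).unique())
                  for col in FACTORS.values() if col in data.columns}
    return out


def stepwise_backward_aic(full_spec: ModelSpec, table: pd.DataFrame,
                          trace: list | None = None) -> ModelSpec:
    """Backward elimination on AIC (ML fits), respecting marginality.

    At each step every removable term (one not nested in a retained
    interaction) is dropped in turn; the drop giving the largest AIC
    decrease is applied, stopping when no drop improves AIC.
    """
    current = full_spec
    current_aic = fit_mixed(current, table, reml=False).aic
    while True:
        best = None
        for term in current.removable_terms():
            cand = current.drop(term)
            aic = fit_mixed(cand, table, reml=False).aic
            if trace is not None:
                trace.append((term, aic))
            if aic < current_aic - 1e-9 and (best is None or aic < best[1]):
                best = (cand, aic, term)
        if best is None:
            return current
        current, current_aic = best[0], best[1]


def likelihood_ratio(reduced: FitResult, full: FitResult) -> tuple[float, int, float]:
    """LRT of a reduced model against a nesting full model (ML fits).

    Returns (statistic, dof, p).  The statistic is 2 * (llf_full -
    llf_reduced) floored at 0; dof is the parameter-count difference.
    """
    if reduced.reml or full.reml:
        raise ValueError("likelihood-ratio comparison requires ML fits")
    if not set(reduced.spec.fixed_terms) <= set(full.spec.fixed_terms):
        raise ValueError("models are not nested")
    dof = full.n_params - reduced.n_params
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if dof == 0 else float(sps.chi2.sf(stat, dof))
    return stat, dof, p


# ---------------------------------------------------------------------------
# Per-term F tests and Tukey HSD on estimated marginal means
# ---------------------------------------------------------------------------


def term_f_tests(fit: FitResult) -> pd.DataFrame:
    """Wald F test per fixed-effect term (residual-dof approximation)."""
    res = fit.result
    di = fit.design_info
    beta = np.asarray(res.fe_params)
    V = np.asarray(res.cov_params())[:len(beta), :len(beta)]
    ddof = fit.resid_dof()
    pos_of = {orig: i for i, orig in enumerate(fit.kept_columns)}
    n_cols = len(di.column_names)
    rows = []
    for name, sl in di.term_name_slices.items():
        if name == "Intercept":
            continue
        idx = np.array([pos_of[j] for j in np.arange(n_cols)[sl]
                        if j in pos_of], dtype=int)
        if idx.size == 0:
            continue  # term fully aliased away
        b = beta[idx]
        Vi = V[np.ix_(idx, idx)]
        q = len(idx)
        try:
            f = float(b @ np.linalg.solve(Vi, b)) / q
        except np.linalg.LinAlgError:
            f = float(b @ np.linalg.pinv(Vi) @ b) / q
        rows.append(dict(term=name, f_value=f, num_dof=q, den_dof=ddof,
                         p_value=float(sps.f.sf(f, q, ddof))))
    return pd.DataFrame(rows)


def emmeans(fit: FitResult, factor: str) -> pd.Series:
    """Estimated marginal means of a factor (balanced over other factors)."""
    col = FACTORS.get(factor, factor)
    levels, means, _ = _emmeans(fit, col)
    return pd.Series(means, index=levels, name="emmean")


def _emmeans(fit: FitResult, factor_col: str) -> tuple[list, np.ndarray, np.ndarray]:
    """Estimated marginal means of a factor over a balanced reference grid."""
    res = fit.result
    levels = fit.levels
    grid = pd.DataFrame(
        list(itertools.product(*levels.values())), columns=list(levels))
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)[:, fit.kept_columns]
    beta = np.asarray(fit.fe_params)
    V = np.asarray(res.cov_params())[:len(beta), :len(beta)]
    fac_levels = levels[factor_col]
    L = np.stack([
        X[(grid[factor_col] == lev).to_numpy()].mean(axis=0)
        for lev in fac_levels])
    means = L @ beta
    cov = L @ V @ L.T
    return fac_levels, means, cov


def _letters(levels: list, means: np.ndarray, sig: np.ndarray) -> dict:
    """Compact letter display: maximal runs of mutually non-significant
    levels (means sorted descending) share a letter."""
    order = np.argsort(-means)
    groups = []
    for start in range(len(order)):
        end = start
        while end + 1 < len(order) and not any(
                sig[order[i], order[end + 1]]
                for i in range(start, end + 1)):
            end += 1
        groups.append(tuple(order[start:end + 1]))
    # drop groups contained in another
    maximal = [g for g in groups
               if not any(set(g) < set(o) for o in groups)]
    seen, uniq = set(), []
    for g in maximal:
        if g not in seen:
            uniq.append(g)
            seen.add(g)
    letters = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", uniq):
        for i in g:
            letters[levels[i]] += letter
    return letters


@dataclass
class TukeyResult:
    factor: str
    gate_f: float
    gate_p: float
    gate_passed: bool
    means: pd.Series
    pairs: pd.DataFrame
    letters: dict


def tukey_hsd(fit: FitResult, factor: str, alpha: float = 0.05) -> TukeyResult:
    """All pairwise Tukey comparisons of one factor's marginal means.

    ``factor`` may be a symbol (GT/GM/MP/EW) or a column name.  The
    comparison is gated on the factor's F test: when the gate fails all
    levels share one letter and no pair is called significant.
    """
    col = FACTORS.get(factor, factor)
    symbol = {v: k for k, v in FACTORS.items()}.get(col, col)
    ftab = term_f_tests(fit)
    main_row = ftab[ftab.term == f"C({col})"]
    gate_f = float(main_row.f_value.iloc[0]) if len(main_row) else np.nan
    gate_p = float(main_row.p_value.iloc[0]) if len(main_row) else np.nan
    gate_passed = bool(gate_p <= alpha) if np.isfinite(gate_p) else False

    levels, means, cov = _emmeans(fit, col)
    k = len(levels)
    ddof = fit.resid_dof()
    rows = []
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(max(1e-300, cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        q = abs(diff) / (se / np.sqrt(2.0))
        p = float(sps.studentized_range.sf(q, k, ddof))
        significant = gate_passed and p <= alpha
        sig[i, j] = sig[j, i] = significant
        rows.append(dict(level_a=levels[i], level_b=levels[j], estimate=diff,
                         se=se, q=q, p_adj=p, significant=significant))
    letters = _letters(levels, means, sig)
    return TukeyResult(
        factor=symbol, gate_f=gate_f, gate_p=gate_p, gate_passed=gate_passed,
        means=pd.Series(means, index=levels, name="emmean"),
        pairs=pd.DataFrame(rows), letters=letters,
    )


# ---------------------------------------------------------------------------
# RMSE
# ---------------------------------------------------------------------------


def rmse(observed, simulated) -> float:
    """Root mean square error between paired observations and simulations."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {sim.shape}")
    if obs.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((obs - sim) ** 2)))


# ---------------------------------------------------------------------------
# Synthetic tables with the factorial random structure (for recovery tests)
# ---------------------------------------------------------------------------

_LEVELS = {
    "trait": ("nonLT", "LT0.9"),
    "maturity": ("short", "medium", "full"),
    "planting": ("May-01", "May-15", "Jun-01"),
    "env": ("WW", "LD", "MD", "ED"),
}


def simulate_factorial_table(
    n_sites: int = 4,
    n_years: int = 6,
    mu: float = 4.0,
    effects: dict | None = None,
    sd_site: float = 0.2,
    sd_year: float = 0.1,
    sd_resid: float = 0.3,
    seed: int = 0,
    response: str = "yield_mg_ha",
) -> pd.DataFrame:
    """Balanced synthetic table with the year-in-location random structure.

    ``effects`` maps a factor-column tuple to a dict of level-tuples ->
    additive effect, e.g. ``{("trait",): {("LT0.9",): 0.3}}`` for a trait
    main effect or ``{("trait", "env"): {("LT0.9", "ED"): 0.5}}`` for an
    interaction.  Used by recovery tests, where the generating
    coefficients are known exactly.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    cells = list(itertools.product(*_LEVELS.values()))
    rows = []
    for s in range(n_sites):
        b_site = rng.normal(0.0, sd_site)
        for y in range(n_years):
            b_year = rng.normal(0.0, sd_year)
            for trait, maturity, planting, env in cells:
                val = mu + b_site + b_year
                level_of = dict(trait=trait, maturity=maturity,
                                planting=planting, env=env)
                for cols, table_ in effects.items():
                    key = tuple(level_of[c] for c in cols)
                    val += table_.get(key, 0.0)
                val += rng.normal(0.0, sd_resid)
                rows.append(dict(site=s, year=y, trait=trait,
                                 maturity=maturity, planting=planting,
                                 env=env, failed=False, **{response: val}))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> Path:
    """Write tidy CSVs plus a plain-text summary; byte-stable given inputs.

    ``tables`` may hold any of: ``runs`` (the factorial table),
    ``relative`` (pairwise percent changes), ``frequencies`` (environment
    frequencies per site), ``sensitivity_moisture``, ``sensitivity_cap``.
    Sections without input are marked absent rather than failing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["limited-transpiration simulation report", "=" * 40, ""]

    runs = tables.get("runs")
    if runs is not None and len(runs):
        runs.to_csv(out_dir / "runs.csv", index=False)
        cell = (runs[~runs.failed]
                .groupby(["trait", "maturity", "planting"])["yield_mg_ha"]
                .mean().reset_index())
        cell.to_csv(out_dir / "mean_yield_by_cell.csv", index=False)
        lines.append(f"factorial runs: {len(runs)} records, "
                     f"{int(runs.failed.sum())} failed seasons")
    else:
        lines.append("factorial runs: absent")

    rel = tables.get("relative")
    if rel is not None and len(rel):
        by_env = (rel.groupby(["trait", "env"])["pct_change"]
                  .agg(mean_pct="mean", sd_pct="std", n="count").reset_index())
        by_env.to_csv(out_dir / "relative_change_by_env.csv", index=False)
        lines.append("relative LT yield change by environment:")
        for r in by_env.itertuples(index=False):
            lines.append(f"  {r.trait} in {r.env}: {r.mean_pct:+.1f}% "
                         f"(sd {r.sd_pct:.1f}, n={r.n})")
    else:
        lines.append("relative change: absent")

    freq = tables.get("frequencies")
    if freq is not None and len(freq):
        freq.to_csv(out_dir / "environment_frequencies.csv")
        lines.append("environment frequencies written")
    else:
        lines.append("environment frequencies: absent")

    for key in ("sensitivity_moisture", "sensitivity_cap"):
        tab = tables.get(key)
        if tab is not None and len(tab):
            tab.to_csv(out_dir / f"{key}.csv", index=False)
            lines.append(f"{key} written ({len(tab)} rows)")
        else:
            lines.append(f"{key}: absent")

    text = "\n".join(lines) + "\n"
    (out_dir / "report.txt").write_text(text)
    return out_dir / "report.txt"


__all__ = [
    "FACTORS", "MODEL_PRESETS", "ModelSpec", "FitResult", "TukeyResult",
    "spec", "fit_mixed", "stepwise_backward_aic", "likelihood_ratio",
    "term_f_tests", "tukey_hsd", "emmeans", "rmse", "simulate_factorial_table", "report",
]
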