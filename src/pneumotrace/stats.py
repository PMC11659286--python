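"""Mixed-effects statistics and reporting.

The study design is repeated measures (epochs or trials within animal)
with group (SPF control vs germ-free) and sex fixed effects.  Outcomes
are analyzed with a linear mixed-effects model (REML, random intercept
per animal) on a chosen transform of the outcome (raw, log10 or square
root), followed by Tukey Honestly-Significant-Difference pairwise
contrasts over the group x sex cells.  Significance is declared at
p < 0.05 on the adjusted p-values.

statsmodels provides the REML fit; the Tukey layer (cell means from the
fitted fixed effects, studentized-range adjustment with containment
degrees of freedom) is implemented here because statsmodels has no
mixed-model post-hoc machinery.  When the random-intercept variance is
estimated at (or collapses to) zero, the model falls back to ordinary
least squares with a warning; in the balanced two-group case the Tukey
p-value then reduces exactly to the pooled-variance two-sample t-test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.stats import studentized_range

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .simulate import CohortDesign, simulate_outcome_table

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "StatResult",
    "fit_lmem",
    "choose_transform",
    "type1_error_suite",
    "render_report",
    "PAPER_TRANSFORMS",
]

TRANSFORMS = ("raw", "log10", "sqrt")

# per-outcome analysis transforms used in reporting: breath timing and
# ventilation/metabolic outcomes on log10, inspiratory duration and tidal
# volume and event rates on sqrt
PAPER_TRANSFORMS: dict[str, str] = {
    "ti_s": "sqrt", "inspiratory_duration": "sqrt",
    "te_s": "log10", "expiratory_duration": "log10",
    "tt_s": "log10", "breath_cycle_duration": "log10",
    "vf": "log10", "ventilatory_frequency": "log10",
    "vt_ml": "sqrt", "vt_ml_per_g": "sqrt", "tidal_volume": "sqrt",
    "ve": "log10", "ve_per_g": "log10", "ventilation": "log10",
    "vo2": "log10", "oxygen_consumption": "log10",
    "ve_over_vo2": "log10",
    "apnea_per100": "sqrt", "sigh_per100": "sqrt",
}


def _apply_transform(y: pd.Series, transform: str) -> pd.Series:
    if transform == "raw":
        return y
    if transform == "log10":
        if (y <= 0).any():
            bad = y.index[y <= 0].tolist()[:5]
            raise ValueError(f"log10 transform needs positive values; "
                             f"offending rows include {bad}")
        return np.log10(y)
    if transform == "sqrt":
        if (y < 0).any():
            bad = y.index[y < 0].tolist()[:5]
            raise ValueError(f"sqrt transform needs nonnegative values; "
                             f"offending rows include {bad}")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class ModelSpec:
    """Specification of one outcome analysis."""

    outcome: str
    transform: str = "raw"
    fixed: tuple[str, ...] = ("group", "sex")
    covariates: tuple[str, ...] = ()
    group_col: str = "animal_id"       # random-intercept grouping
    random_intercept: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def formula(self) -> str:
        terms = ["*".join(f"C({f})" for f in self.fixed)] if self.fixed else ["1"]
        terms += list(self.covariates)
        return f"__y__ ~ {' + '.join(terms)}"


@dataclass
class StatResult:
    outcome: str
    transform: str
    fixed_effects: pd.DataFrame        # term, estimate, se
    contrasts: pd.DataFrame            # pair, estimate, se, p_unadj, p_tukey
    cell_means: pd.DataFrame           # cell, estimate, se
    diagnostics: dict                  # per-transform residual diagnostics
    df_method: str
    df: float
    used_mixed: bool
    alpha: float = 0.05
    # fitted-quantity internals for derived contrasts
    _L: np.ndarray | None = None
    _beta: np.ndarray | None = None
    _cov: np.ndarray | None = None
    _cells: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.contrasts[self.contrasts["p_tukey"] < self.alpha]

    def main_effect(self, factor: str, hi: str, lo: str) -> dict:
        """Marginal effect hi - lo of one factor (cell means averaged
        over the other factors), with SE and a 95% CI at the model df."""
        cells = self._cells
        w = np.zeros(len(cells))
        sel_hi = cells[factor].astype(str) == hi
        sel_lo = cells[factor].astype(str) == lo
        if not sel_hi.any() or not sel_lo.any():
            raise ValueError(f"levels {hi!r}/{lo!r} not found for {factor!r}")
        w[sel_hi.to_numpy()] = 1.0 / sel_hi.sum()
        w[sel_lo.to_numpy()] = -1.0 / sel_lo.sum()
        l_vec = w @ self._L
        est = float(l_vec @ self._beta)
        se = float(np.sqrt(l_vec @ self._cov @ l_vec))
        tcrit = spstats.t.ppf(1 - 0.025, self.df)
        return {"estimate": est, "se": se, "df": self.df,
                "ci_low": est - tcrit * se, "ci_high": est + tcrit * se}


def _residual_diagnostics(resid: np.ndarray) -> dict:
    """QQ correlation (normal probability plot correlation) and absolute
    skewness of residuals."""
    r = np.sort(np.asarray(resid, dtype=float))
    n = len(r)
    if n < 4 or np.std(r) == 0:
        return {"qq_corr": float("nan"), "abs_skew": float("nan")}
    q = spstats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return {"qq_corr": float(np.corrcoef(q, r)[0, 1]),
            "abs_skew": float(abs(spstats.skew(r)))}


def _fit_engine(data: pd.DataFrame, spec: ModelSpec):
    """REML mixed fit with OLS fallback.

    Returns ``(result, used_mixed, dfinfo)`` where dfinfo carries what
    the Satterthwaite-type contrast df needs: the variance components
    and their degrees of freedom.
    """
    d = data.copy()
    d["__y__"] = _apply_transform(d[spec.outcome].astype(float), spec.transform)
    formula = spec.formula()
    n_cells = d.groupby(list(spec.fixed)).ngroups if spec.fixed else 1
    use_mixed = spec.random_intercept
    n_groups = d[spec.group_col].nunique()
    if use_mixed and n_groups == len(d):
        # a mixed model needs replication within animals
        use_mixed = False
    if use_mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(formula, d, groups=d[spec.group_col])
                res = model.fit(reml=True)
                sigma2_b = float(np.asarray(res.cov_re).ravel()[0])
                if not np.isfinite(sigma2_b) or sigma2_b <= 1e-10 * res.scale:
                    raise ValueError("singular random-effect fit")
                n_per_cell = (d.groupby(list(spec.fixed))[spec.group_col]
                              .nunique().mean() if spec.fixed else n_groups)
                dfinfo = {
                    "sigma2_b": sigma2_b,
                    "sigma2_e": float(res.scale),
                    "df_between": max(n_groups - n_cells, 1),
                    "df_within": max(len(d) - n_groups, 1),
                    "n_animals_per_cell": float(n_per_cell),
                    "obs_per_animal": len(d) / n_groups,
                }
                return res, True, dfinfo
            except Exception as exc:   # singular / convergence failure
                log.warning("mixed fit failed (%s); falling back to fixed-"
                            "effects-only OLS", exc)
    res = smf.ols(formula, d).fit()
    return res, False, {"df_fixed": float(res.df_resid)}


def _satterthwaite_df(dfinfo: dict) -> float:
    """Satterthwaite-type degrees of freedom for a difference of cell
    means under the random-intercept model: the between-animal and
    within-animal variance contributions are weighted by their own df.
    """
    if "df_fixed" in dfinfo:
        return dfinfo["df_fixed"]
    n = max(float(dfinfo["n_animals_per_cell"]), 2.0)
    m = max(float(dfinfo["obs_per_animal"]), 1.0)
    vb = 2.0 * dfinfo["sigma2_b"] / n
    vw = 2.0 * dfinfo["sigma2_e"] / (n * m)
    denom = vb ** 2 / dfinfo["df_between"] + vw ** 2 / dfinfo["df_within"]
    if denom <= 0:
        return float(dfinfo["df_between"])
    return float((vb + vw) ** 2 / denom)


def _cell_design(res, cells: pd.DataFrame) -> np.ndarray:
    """Fixed-effects design rows for the given cells via the fitted
    model's design info (covariates, if any, must be columns)."""
    from patsy import build_design_matrices
    di = res.model.data.design_info
    return np.asarray(build_design_matrices([di], cells)[0])


def fit_lmem(data: pd.DataFrame, spec: ModelSpec) -> StatResult:
    """Fit the mixed model for one outcome and compute Tukey HSD
    contrasts over the cells of the fixed-effect design.

    Contrast p-values use the studentized-range distribution over the
    ``k`` cell means with containment degrees of freedom (number of
    animals minus number of cells) for the mixed fit, or the residual
    degrees of freedom for the OLS fallback.  Unadjusted two-sided
    t-test p-values are reported alongside; Tukey p >= unadjusted p
    always.
    """
    for col in (spec.outcome, *spec.fixed, *spec.covariates):
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from data")
    if spec.fixed:
        counts = data.groupby(list(spec.fixed))[spec.group_col].nunique()
        if (counts < 2).any():
            raise ValueError("need >= 2 animals per fixed-effect cell")
    res, used_mixed, dfinfo = _fit_engine(data, spec)
    df = _satterthwaite_df(dfinfo)

    # cells of the fixed-effect design, in deterministic order
    if spec.fixed:
        levels = [sorted(data[f].astype(str).unique()) for f in spec.fixed]
        cells = pd.DataFrame(
            [dict(zip(spec.fixed, combo)) for combo in product(*levels)])
    else:
        cells = pd.DataFrame([{}])
    for cov in spec.covariates:
        cells[cov] = float(data[cov].mean())
    labels = cells[list(spec.fixed)].astype(str).agg(":".join, axis=1) \
        if spec.fixed else pd.Series(["all"])

    L = _cell_design(res, cells)
    beta = np.asarray(res.params)[:L.shape[1]]
    cov = np.asarray(res.cov_params())[:L.shape[1], :L.shape[1]]
    est = L @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    cell_means = pd.DataFrame({"cell": labels, "estimate": est, "se": se})

    k = len(cells)
    rows = []
    # degenerate scale (e.g. exactly constant outcome): differences and
    # their SEs are both numerically zero
    zero_tol = 1e-9 * max(1.0, float(np.abs(est).max()))
    for i, j in combinations(range(k), 2):
        l_diff = L[i] - L[j]
        d_est = float(l_diff @ beta)
        d_se = float(np.sqrt(max(l_diff @ cov @ l_diff, 0.0)))
        if d_se <= zero_tol and abs(d_est) <= zero_tol:
            tval, p_un, p_tk = 0.0, 1.0, 1.0
        elif d_se == 0:
            tval, p_un, p_tk = np.inf, 0.0, 0.0
        else:
            tval = d_est / d_se
            p_un = float(2 * spstats.t.sf(abs(tval), df))
            p_tk = float(studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df)) \
                if k > 1 else p_un
        rows.append({"pair": f"{labels[i]} - {labels[j]}",
                     "estimate": d_est, "se": d_se, "t": tval,
                     "p_unadj": p_un, "p_tukey": max(p_tk, p_un)})
    contrasts = pd.DataFrame(rows)

    fe = pd.DataFrame({
        "term": res.model.data.design_info.column_names,
        "estimate": beta,
        "se": np.sqrt(np.diag(cov)),
    })
    diag = {spec.transform: _residual_diagnostics(np.asarray(res.resid))}
    cells_out = cells.copy()
    cells_out["cell"] = labels.to_numpy()
    return StatResult(
        outcome=spec.outcome, transform=spec.transform, fixed_effects=fe,
        contrasts=contrasts, cell_means=cell_means, diagnostics=diag,
        df_method="Satterthwaite-type (variance-component weighted)"
        if used_mixed else "OLS residual", df=df, used_mixed=used_mixed,
        alpha=spec.alpha, _L=L, _beta=beta, _cov=cov, _cells=cells_out)


def choose_transform(data: pd.DataFrame, spec: ModelSpec,
                     candidates: tuple[str, ...] = TRANSFORMS,
                     mode: str = "table") -> tuple[str, dict]:
    """Choose the analysis transform for an outcome.

    ``mode='table'`` returns the study's per-outcome transform table
    entry (falling back to automatic selection for unknown outcomes);
    ``mode='auto'`` fits every candidate and picks the one maximizing
    the residual QQ correlation, ties broken toward raw.  Diagnostics
    for every evaluated candidate are returned either way.
    """
    diagnostics: dict[str, dict] = {}
    for cand in candidates:
        try:
            res, _, _ = _fit_engine(data, ModelSpec(**{**spec.__dict__,
                                                       "transform": cand}))
        except ValueError as exc:
            log.info("transform %s skipped: %s", cand, exc)
            diagnostics[cand] = {"qq_corr": float("nan"),
                                 "abs_skew": float("nan"), "skipped": True}
            continue
        diagnostics[cand] = _residual_diagnostics(np.asarray(res.resid))
    if mode == "table" and spec.outcome in PAPER_TRANSFORMS:
        return PAPER_TRANSFORMS[spec.outcome], diagnostics
    usable = {c: d for c, d in diagnostics.items()
              if np.isfinite(d.get("qq_corr", float("nan")))}
    if not usable:
        return "raw", diagnostics
    best = max(usable, key=lambda c: (usable[c]["qq_corr"], c == "raw"))
    # near-ties (transforms that are locally linear on the data's range
    # give indistinguishable residuals) break toward raw
    if "raw" in usable and \
            usable["raw"]["qq_corr"] >= usable[best]["qq_corr"] - 1e-3:
        best = "raw"
    return best, diagnostics


def type1_error_suite(design: CohortDesign, n_reps: int = 500,
                      seed: int = 0, grand_mean: float = 10.0,
                      n_obs: int = 5, alpha: float = 0.05) -> float:
    """Fraction of null replicates (zero group and sex effects) in which
    any between-group Tukey-adjusted contrast is significant — the
    family-wise type-I error of the LMEM + Tukey stack."""
    if design.group_effect != 0 or design.sex_effect != 0:
        raise ValueError("type-I error suite requires zero effects")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        tab = simulate_outcome_table(design, grand_mean, n_obs,
                                     seed=int(rng.integers(0, 2**31 - 1)))
        res = fit_lmem(tab, ModelSpec(outcome="outcome"))
        if alpha > 0 and (res.contrasts["p_tukey"] < alpha).any():
            rejections += 1
    return rejections / n_reps


def render_report(results: list[StatResult], summaries: pd.DataFrame | None,
                  out_dir: str | Path, provenance: dict | None = None,
                  ) -> dict[str, Path]:
    """Render machine- and human-readable reports.

    Writes ``report.json`` (full results), ``contrasts.tsv`` and
    ``cell_means.tsv``; regenerating from identical inputs is
    byte-identical.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_contrasts = []
    all_cells = []
    payload: dict = {"provenance": provenance or {}, "outcomes": []}
    for r in results:
        c = r.contrasts.copy()
        c.insert(0, "outcome", r.outcome)
        all_contrasts.append(c)
        m = r.cell_means.copy()
        m.insert(0, "outcome", r.outcome)
        all_cells.append(m)
        payload["outcomes"].append({
            "outcome": r.outcome,
            "transform": r.transform,
            "df_method": r.df_method,
            "df": r.df,
            "used_mixed": r.used_mixed,
            "diagnostics": r.diagnostics,
            "n_contrasts": int(len(r.contrasts)),
            "significant": r.significant["pair"].tolist()
            if len(r.contrasts) else [],
            "note": None if len(r.contrasts) else "no contrasts",
        })
    paths = {}
    paths["json"] = out_dir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    paths["contrasts"] = out_dir / "contrasts.tsv"
    (pd.concat(all_contrasts, ignore_index=True) if all_contrasts
     else pd.DataFrame()).to_csv(paths["contrasts"], sep="\t", index=False,
                                 float_format="%.6g")
    paths["cell_means"] = out_dir / "cell_means.tsv"
    cells = (pd.concat(all_cells, ignore_index=True) if all_cells
             else pd.DataFrame())
    if summaries is not None and len(cells):
        pass  # raw-scale group means live in the summaries table itself
    cells.to_csv(paths["cell_means"], sep="\t", index=False, float_format="%.6g")
    txt = out_dir / "report.txt"
    with open(txt, "w") as fh:
        for r in results:
            fh.write(f"== {r.outcome} (transform={r.transform}, "
                     f"df={r.df:.0f} [{r.df_method}]) ==\n")
            if len(r.contrasts) == 0:
                fh.write("  no contrasts\n")
            for _, row in (r.contrasts.iterrows() if len(r.contrasts) else []):
                star = " *" if row["p_tukey"] < r.alpha else ""
                fh.write(f"  {row['pair']}: {row['estimate']:+.4g} "
                         f"(p_tukey={row['p_tukey']:.4g}){star}\n")
    paths["txt"] = txt
    return paths
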