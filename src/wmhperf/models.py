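"""Mixed-effects models over the ROI and lesion tables.

Three model families, all linear mixed models with per-subject random
intercepts fit by REML, plus two supplementary analyses:

* tissue x location: log rCBF ~ tissue + location, tissues (WMH, P4, P8,
  NAWM) x locations (JV, PV, D); default references NAWM and JV, so the
  deep coefficient is the D-vs-JV log-rCBF offset.
* volume x location: log rCBF ~ centred log rVol * location with deep as
  the reference location, so the JV and PV interaction coefficients are the
  slope differences relative to deep WM.
* lesion longitudinal: per (location, tissue), lesion log rCBF ~
  category * session with stagnant / baseline references; the category
  main effects are the growing-vs-stagnant and new-vs-stagnant *baseline*
  mean differences reported with Wald 95% CIs.
* a centroid-distance covariate model and a one-way ANOVA of lesion
  volume by location.

Confidence intervals are Wald (estimate +/- 1.96 SE); p-values within each
reported contrast family are corrected by Benjamini-Hochberg by default
(Holm / Bonferroni selectable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z_95 = 1.959963984540054


@dataclass
class ModelResult:
    """Fixed-effect table of one fitted mixed model."""

    model_id: str
    params: pd.DataFrame  # index: term; columns: estimate, se, t, ci_low, ci_high, p
    n_obs: int
    n_groups: int
    reference_levels: dict[str, str] = field(default_factory=dict)
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str, model_id: str, reference_levels: dict[str, str]) -> ModelResult:
    data = data.dropna(subset=_formula_columns(formula, data)).copy()
    if data.empty:
        raise ValueError(f"{model_id}: no complete observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[groups])
        try:
            fit = model.fit(reml=True, method="bfgs")
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
        fe = fit.fe_params
        se = fit.bse_fe
        tvals = fe / se
    table = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "t": tvals,
            "ci_low": fe - Z_95 * se,
            "ci_high": fe + Z_95 * se,
            "p": 2 * stats.norm.sf(np.abs(tvals)),
        }
    )
    notes = []
    if not fit.converged:
        notes.append("optimizer reported non-convergence; estimates may sit on a variance boundary")
    return ModelResult(
        model_id=model_id,
        params=table,
        n_obs=int(fit.nobs),
        n_groups=len(np.unique(data[groups])),
        reference_levels=reference_levels,
        converged=bool(fit.converged),
        notes=notes,
    )


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c in formula]


def fit_tissue_location_model(
    table: pd.DataFrame,
    tissue_ref: str = "NAWM",
    location_ref: str = "JV",
    tissues: tuple[str, ...] = ("WMH", "P4", "P8", "NAWM"),
) -> ModelResult:
    """log rCBF ~ tissue + location with a subject random intercept."""
    data = table[table["tissue"].isin(tissues) & table["region"].isin(["JV", "PV", "D"])]
    formula = (
        f"log_rcbf ~ C(tissue, Treatment('{tissue_ref}')) + C(region, Treatment('{location_ref}'))"
    )
    res = _fit_mixedlm(formula, data, "subject", "tissue_location", {"tissue": tissue_ref, "region": location_ref})
    res.params.index = [_clean_term(t) for t in res.params.index]
    return res


def fit_volume_location_model(
    table: pd.DataFrame, location_ref: str = "D", min_subjects_per_region: int = 3
) -> ModelResult:
    """log rCBF ~ centred log rVol * location, subject random intercept.

    With deep as the reference, the ``region[JV]:log_rvol_centered`` and
    ``region[PV]:log_rvol_centered`` terms are the JV-D and PV-D slope
    differences.  Regions contributed by fewer than ``min_subjects_per_region``
    subjects are dropped with a warning.
    """
    data = table[
        (table["tissue"] == "WMH") & table["region"].isin(["JV", "PV", "D"])
    ].dropna(subset=["log_rcbf", "log_rvol_centered"])
    keep = []
    for region, grp in data.groupby("region"):
        if grp["subject"].nunique() < min_subjects_per_region:
            warnings.warn(f"region {region} has <{min_subjects_per_region} subjects; dropped", stacklevel=2)
        else:
            keep.append(region)
    data = data[data["region"].isin(keep)]
    if data["region"].nunique() == 1:
        # degenerate single-location design: a plain random-intercept slope model
        formula = "log_rcbf ~ log_rvol_centered"
        res = _fit_mixedlm(formula, data, "subject", "volume_location", {"region": location_ref})
    else:
        formula = f"log_rcbf ~ C(region, Treatment('{location_ref}')) * log_rvol_centered"
        res = _fit_mixedlm(formula, data, "subject", "volume_location", {"region": location_ref})
    res.params.index = [_clean_term(t) for t in res.params.index]
    return res


def fit_lesion_longitudinal_model(
    lesion_table: pd.DataFrame,
    location: str,
    tissue: str,
    category_ref: str = "stagnant",
    session_ref: str = "baseline",
) -> ModelResult:
    """Per (location, tissue) model: log rCBF ~ category * session.

    Rows are one lesion (or its penumbra ROI) per session; "new" lesions
    contribute baseline rows through back-projection of the follow-up
    footprint.  With stagnant/baseline references, the ``category[growing]``
    and ``category[new]`` main effects are the baseline mean differences
    versus stagnant lesions.  A category observed on fewer than two lesions
    makes its contrast non-estimable and is noted.
    """
    data = lesion_table[
        (lesion_table["location"] == location)
        & (lesion_table["tissue"] == tissue)
        & lesion_table["category"].isin(["stagnant", "growing", "new"])
    ].dropna(subset=["log_rcbf"])
    notes = []
    for cat in ("stagnant", "growing", "new"):
        n_lesions = data.loc[data["category"] == cat, "lesion"].nunique() if "lesion" in data else 0
        if n_lesions < 2:
            notes.append(f"category {cat!r} has {n_lesions} lesions; its contrast is non-estimable")
    formula = (
        f"log_rcbf ~ C(category, Treatment('{category_ref}')) * C(session, Treatment('{session_ref}'))"
    )
    res = _fit_mixedlm(
        formula, data, "subject", f"lesion_longitudinal[{location},{tissue}]",
        {"category": category_ref, "session": session_ref},
    )
    res.notes.extend(notes)
    res.params.index = [_clean_term(t) for t in res.params.index]
    return res


def centroid_distance_model(lesion_table: pd.DataFrame) -> ModelResult:
    """Lesion log rCBF on centroid ventricular distance, subject intercepts."""
    data = lesion_table.dropna(subset=["log_rcbf", "centroid_distance_mm"])
    res = _fit_mixedlm(
        "log_rcbf ~ centroid_distance_mm", data, "subject", "centroid_distance", {}
    )
    return res


def anova_volume_by_location(table: pd.DataFrame, value: str = "log_rvol") -> tuple[float, float]:
    """One-way ANOVA of (log) WMH volume across JV/PV/D locations."""
    data = table[table["tissue"] == "WMH"].dropna(subset=[value])
    if data["region"].isin(["JV", "PV", "D"]).any():
        data = data[data["region"].isin(["JV", "PV", "D"])]
    groups = [grp[value].to_numpy() for _, grp in data.groupby("region") if len(grp)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two location groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def correct_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity-corrected p-values for one contrast family.

    Default Benjamini-Hochberg; ``holm`` and ``bonferroni`` selectable.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def _clean_term(term: str) -> str:
    """'C(region, Treatment('D'))[T.JV]' -> 'region[JV]'; interactions joined by ':'."""
    parts = term.split(":")
    out = []
    for part in parts:
        part = part.strip()
        if part.startswith("C(") and "[T." in part:
            var = part[2:].split(",")[0].strip()
            level = part.split("[T.")[1].rstrip("]")
            out.append(f"{var}[{level}]")
        else:
            out.append(part)
    return ":".join(out)


def table2_report(lesion_table: pd.DataFrame, correction: str = "bh") -> pd.DataFrame:
    """Baseline growing/new-vs-stagnant contrasts per location x tissue.

    Nine rows (3 locations x 3 tissues).  P-values are corrected within each
    category's nine contrasts, the family implied by reporting one corrected
    column per category.
    """
    rows = []
    for location in ("JV", "PV", "D"):
        for tissue in ("WMH", "P4", "P8"):
            try:
                res = fit_lesion_longitudinal_model(lesion_table, location, tissue)
            except (ValueError, np.linalg.LinAlgError) as err:
                # small cohorts can lack a whole location x tissue cell
                rows.append({"location": location, "tissue": tissue, "intercept": np.nan, "note": str(err)})
                continue
            row = {"location": location, "tissue": tissue, "intercept": res.estimate("Intercept")}
            for cat in ("growing", "new"):
                term = f"category[{cat}]"
                if term in res.params.index:
                    lo, hi = res.ci(term)
                    row.update(
                        {
                            f"{cat}_diff": res.estimate(term),
                            f"{cat}_ci_low": lo,
                            f"{cat}_ci_high": hi,
                            f"{cat}_p": float(res.params.loc[term, "p"]),
                        }
                    )
                else:
                    row.update({f"{cat}_diff": np.nan, f"{cat}_ci_low": np.nan, f"{cat}_ci_high": np.nan, f"{cat}_p": np.nan})
            rows.append(row)
    report = pd.DataFrame(rows)
    for cat in ("growing", "new"):
        mask = report[f"{cat}_p"].notna()
        report.loc[mask, f"{cat}_p_corrected"] = correct_pvalues(report.loc[mask, f"{cat}_p"], method=correction)
    return report
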