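"""Dual-level survival screening for breast-cancer-specific survival.

Every feature — whole-gene expression (GE), exon expression (EE) or
splicing index (SI) — is screened independently as the predictor of a
Cox proportional-hazards model of breast-cancer-specific survival
(deaths from other causes are censoring events), with a Wald test on
its coefficient and Benjamini-Hochberg q-values over the screen
(association threshold q < 0.1).  Two models are supported:

``univariate``
    hazard ~ feature
``adjusted``
    hazard ~ feature + lymphocytic infiltration class, where the
    percentage of tumour-infiltrating lymphocytes is dichotomized at
    15% ("low" < 15% <= "high"); a feature whose univariate association
    vanishes after adjustment is acting as a surrogate for lymphocytic
    abundance.

Predictors are standardized by default, so hazard ratios are per SD of
the feature and comparable across the GE/EE/SI scales.  Fits use the
partial likelihood with Efron tie handling (lifelines).  Genes are
reported SI-associated when the minimum-q probe of the gene passes the
threshold, mirroring probe-tested, gene-reported bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .errors import ConfigurationError, DataError

LYMPH_CUTOFF_PCT = 15.0
REQUIRED_CLINICAL = ("bcss_time_months", "bcss_event")


def lymph_class_from_pct(lymph_pct) -> pd.Series:
    """Dichotomize lymphocytic infiltration: < 15% low, >= 15% high."""
    pct = pd.Series(lymph_pct).astype(float)
    return pd.Series(np.where(pct < LYMPH_CUTOFF_PCT, "low", "high"), index=pct.index)


def _check_clinical(clinical: pd.DataFrame):
    for col in REQUIRED_CLINICAL:
        if col not in clinical.columns:
            raise DataError(f"clinical table missing column {col!r}")
    if (clinical["bcss_time_months"] <= 0).any():
        raise DataError("survival times must be positive")


def cox_fit(
    feature_values: pd.Series,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    standardize: bool = True,
) -> dict:
    """Cox proportional-hazards fit for one feature; Wald test on its beta.

    ``covariates`` may include ``"lymph_class"`` (dichotomized at 15%,
    entered as a high-vs-low indicator).  Efron tie handling throughout.
    Returns beta, hr, 95% CI, Wald p and standard error.
    """
    _check_clinical(clinical)
    x = pd.Series(feature_values).astype(float)
    if not x.index.equals(clinical.index):
        x = x.reindex(clinical.index)
        if x.isna().any():
            raise DataError("feature values do not cover all clinical samples")
    if int(clinical["bcss_event"].sum()) < 2:
        raise DataError("fewer than 2 events; cannot fit a Cox model")
    sd = x.std(ddof=0)
    if sd == 0:
        raise DataError("zero variance predictor")
    if standardize:
        x = (x - x.mean()) / sd
    frame = pd.DataFrame(
        {
            "feature": x,
            "time": clinical["bcss_time_months"].astype(float),
            "event": clinical["bcss_event"].astype(int),
        }
    )
    for cov in covariates:
        if cov == "lymph_class":
            if "lymph_class" in clinical.columns:
                cls = clinical["lymph_class"]
            elif "lymph_pct" in clinical.columns:
                cls = lymph_class_from_pct(clinical["lymph_pct"])
            else:
                raise DataError("lymph_class covariate requested but no lymphocyte data")
            frame["lymph_high"] = (cls == "high").astype(float)
        else:
            if cov not in clinical.columns:
                raise DataError(f"covariate {cov!r} not in clinical table")
            frame[cov] = clinical[cov].astype(float)
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(
            frame, duration_col="time", event_col="event",
            fit_options={"precision": 1e-12},
        )
    row = fitter.summary.loc["feature"]
    return {
        "beta": float(row["coef"]),
        "se": float(row["se(coef)"]),
        "hr": float(row["exp(coef)"]),
        "hr_ci95_lo": float(row["exp(coef) lower 95%"]),
        "hr_ci95_hi": float(row["exp(coef) upper 95%"]),
        "wald_p": float(row["p"]),
        "n": int(len(frame)),
        "n_events": int(frame["event"].sum()),
        "model": "adjusted" if covariates else "univariate",
    }


def survival_screen(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    level: str = "GE",
    model: str = "univariate",
    annotation: pd.DataFrame | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cox/Wald screen of every matrix feature with BH q-values.

    One row per feature; features failing the Cox preconditions (zero
    variance, too few events) are recorded with NA statistics and a
    reason rather than dropped silently.  ``model="adjusted"`` adds the
    lymphocyte class as a covariate.  Output metadata records whether
    predictors were standardized (per-SD hazard ratios).
    """
    if model not in ("univariate", "adjusted"):
        raise ConfigurationError(f"unknown model {model!r}")
    if not matrix.columns.equals(clinical.index):
        if set(matrix.columns) != set(clinical.index):
            raise DataError("matrix samples and clinical samples differ")
        clinical = clinical.loc[matrix.columns]
    covariates = ("lymph_class",) if model == "adjusted" else ()
    rows = []
    for feature_id, values in matrix.iterrows():
        rec = {"feature_id": feature_id, "level": level, "model": model, "reason": ""}
        try:
            rec.update(cox_fit(values, clinical, covariates, standardize=standardize))
        except DataError as exc:
            rec.update(
                beta=np.nan, se=np.nan, hr=np.nan, hr_ci95_lo=np.nan,
                hr_ci95_hi=np.nan, wald_p=np.nan, reason=str(exc),
            )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("feature_id")
    from .differential import bh_adjust

    ok = out["wald_p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "wald_p"].to_numpy())
    if annotation is not None:
        out.insert(0, "gene_id", annotation.reindex(out.index)["gene_id"])
    out.attrs["standardized"] = standardize
    return out


@dataclass
class SurvivalCategoryCounts:
    """Counts of genes associated with survival at the GE and/or SI level."""

    n_ge_assoc: int
    n_si_assoc: int
    n_both: int

    def __post_init__(self):
        if self.n_both > min(self.n_ge_assoc, self.n_si_assoc):
            raise DataError("n_both exceeds a marginal association count")
        if min(self.n_ge_assoc, self.n_si_assoc, self.n_both) < 0:
            raise DataError("negative association counts")

    @property
    def n_ge_only(self) -> int:
        return self.n_ge_assoc - self.n_both

    @property
    def n_si_only(self) -> int:
        return self.n_si_assoc - self.n_both

    def as_dict(self) -> dict:
        return {
            "n_ge_assoc": self.n_ge_assoc,
            "n_si_assoc": self.n_si_assoc,
            "n_both": self.n_both,
            "n_ge_only": self.n_ge_only,
            "n_si_only": self.n_si_only,
        }


def categorize_survival_genes(
    ge_screen: pd.DataFrame,
    si_screen: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    q_threshold: float = 0.1,
) -> SurvivalCategoryCounts:
    """Partition genes by which survival screens they pass.

    A gene is GE-associated when its gene-level q passes the threshold,
    and SI-associated when its minimum-q probe passes (probe-level BH
    across the whole SI screen).  ``si_screen`` must carry a ``gene_id``
    column or be accompanied by a probe annotation.
    """
    ge_genes = set(ge_screen.index[ge_screen["q"] < q_threshold])
    if "gene_id" in si_screen.columns:
        gene_of = si_screen["gene_id"]
    elif annotation is not None:
        gene_of = annotation.reindex(si_screen.index)["gene_id"]
    else:
        raise DataError("si_screen needs a gene_id column or a probe annotation")
    passing = si_screen["q"] < q_threshold
    si_genes = set(gene_of[passing])
    return SurvivalCategoryCounts(
        n_ge_assoc=len(ge_genes),
        n_si_assoc=len(si_genes),
        n_both=len(ge_genes & si_genes),
    )


def adjusted_screen_comparison(
    univariate_table: pd.DataFrame,
    adjusted_table: pd.DataFrame,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Which univariate hits survive lymphocyte adjustment.

    Returns a per-feature table of significance flags under both models;
    the retained fraction (significant adjusted / significant univariate)
    is stored in ``.attrs["retained_fraction"]``.
    """
    if not univariate_table.index.equals(adjusted_table.index):
        if set(univariate_table.index) != set(adjusted_table.index):
            raise DataError("univariate and adjusted tables cover different features")
        adjusted_table = adjusted_table.loc[univariate_table.index]
    out = pd.DataFrame(
        {
            "sig_univariate": univariate_table["q"] < q_threshold,
            "sig_adjusted": adjusted_table["q"] < q_threshold,
        },
        index=univariate_table.index,
    )
    out["retained"] = out["sig_univariate"] & out["sig_adjusted"]
    n_uni = int(out["sig_univariate"].sum())
    out.attrs["retained_fraction"] = float(out["retained"].sum() / n_uni) if n_uni else np.nan
    return out


def tertile_groups(values) -> pd.Series:
    """Split values into low/mid/high tertiles; ties go to the lower group.

    Cuts at the empirical 1/3 and 2/3 quantiles: low = values <= q1,
    mid = q1 < values <= q2, high = values > q2.
    """
    x = pd.Series(values).astype(float).dropna()
    if len(x) < 3:
        raise DataError("tertile_groups needs >= 3 non-missing values")
    q1, q2 = np.quantile(x.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(x <= q1, "low", np.where(x <= q2, "mid", "high"))
    return pd.Series(labels, index=x.index, name="tertile")


def km_estimate(groups, clinical: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit estimate per group with Greenwood variance.

    Returns, per group, a step function indexed by event/censoring time
    with the survival probability, Greenwood variance and risk-set size.
    """
    _check_clinical(clinical)
    labels = pd.Series(groups)
    if not labels.index.equals(clinical.index):
        labels = labels.reindex(clinical.index)
    out = {}
    for name, idx in labels.groupby(labels).groups.items():
        sub = clinical.loc[idx]
        if len(sub) == 0:
            raise DataError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["bcss_time_months"], sub["bcss_event"], label=str(name))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d))) over event times
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = table["observed"] / (
                table["at_risk"] * (table["at_risk"] - table["observed"])
            )
        greenwood = surv**2 * terms.fillna(0).cumsum()
        out[name] = pd.DataFrame(
            {
                "survival": surv,
                "greenwood_var": greenwood,
                "at_risk": table["at_risk"],
                "observed": table["observed"],
            }
        )
    if len(out) == 0:
        raise DataError("no groups supplied")
    return out


def annotate_lymphocytic(
    gene_list,
    lymph_expression: pd.Series | None = None,
    lymph_gene_sets: dict[str, set] | None = None,
    count_threshold: float = 10,
) -> pd.DataFrame:
    """Flag genes as lymphocyte-associated.

    A gene is flagged when its read count in a user-supplied lymphoid-
    tissue expression table reaches ``count_threshold`` (>= 10 by
    default) OR it is a member of any supplied lymphocyte-related gene
    set.  At least one of the two resources must be given.
    """
    if lymph_expression is None and lymph_gene_sets is None:
        raise DataError("supply a lymphoid expression table and/or lymphocyte gene sets")
    set_members: dict[str, str] = {}
    if lymph_gene_sets:
        for set_name, members in lymph_gene_sets.items():
            for g in members:
                set_members.setdefault(g, set_name)
    rows = []
    for gene in gene_list:
        by_expr = bool(
            lymph_expression is not None
            and gene in lymph_expression.index
            and float(lymph_expression.loc[gene]) >= count_threshold
        )
        in_set = set_members.get(gene)
        sources = [s for s, hit in (("expression", by_expr), (in_set, in_set)) if hit]
        rows.append(
            {
                "gene_id": gene,
                "lymphocytic": by_expr or in_set is not None,
                "source": ";".join(str(s) for s in sources),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
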