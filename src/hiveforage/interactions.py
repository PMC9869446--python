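"""Descriptive analysis of bee-flower visitation tables.

The input is one row per captured bee: its species, genus and sociality
(solitary or eusocial), proboscis length in mm, the plant species it was
caught on, the flower's symmetry (radial or bilateral) and corolla tube
length in mm, plus sampling round and plot labels.  Bilateral symmetry and
deep corolla tubes (strictly longer than 3 mm, the median tube length in
the field data this schema mirrors) are the two proxies for morphological
flower complexity.

Group summaries are species-level by default: each bee species contributes
one proportion (or one mean), and the group mean +/- s.e. is the unweighted
mean across species with ``s.e. = sd / sqrt(n_species)``.  Visit-weighted
variants are reported alongside, since either convention is defensible for
a visitation table.

``fit_choice_regression`` is a deliberately simplified stand-in for a
phylogenetic mixed model: an ordinary maximum-likelihood logistic regression
of flower complexity on sociality, proboscis length and their interaction,
with no random effects.  It does not account for phylogenetic or
repeated-measures correlation, so its standard errors are too small whenever
species-level random variation exists; it is intended for synthetic-data
calibration and sign/direction reporting, not for inference on field data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "REQUIRED_COLUMNS",
    "DEEP_THRESHOLD_MM",
    "read_interactions",
    "code_complexity",
    "complexity_counts",
    "per_species_proportions",
    "group_mean_corolla",
    "size_class_summary",
    "fit_choice_regression",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("bee_species", "sociality", "plant_species", "symmetry")
OPTIONAL_COLUMNS = ("bee_genus", "proboscis_mm", "corolla_mm", "round", "plot")

#: corolla tubes strictly longer than this are coded "deep"
DEEP_THRESHOLD_MM = 3.0

PROBOSCIS_BINS = (0.0, 3.0, 6.0, 9.0, 12.0)

_SOCIALITY = {"solitary", "eusocial"}
_SYMMETRY = {"radial", "bilateral"}


def read_interactions(path_or_buffer) -> pd.DataFrame:
    """Read a visitation CSV into a typed interaction table.

    Mandatory columns: ``bee_species, sociality, plant_species, symmetry``.
    Rows whose sociality is not exactly solitary/eusocial (intermediate
    sociality, blanks, typos) are dropped with a logged count, as are rows
    with unrecognizable symmetry.  Missing trait columns are filled with NA.
    """
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = pd.NA

    n0 = len(df)
    df["sociality"] = df["sociality"].astype("string").str.strip().str.lower()
    df["symmetry"] = df["symmetry"].astype("string").str.strip().str.lower()
    keep = df["sociality"].isin(_SOCIALITY) & df["symmetry"].isin(_SYMMETRY)
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("dropped %d rows with unparseable sociality/symmetry", dropped)
    df = df.loc[keep].reset_index(drop=True)
    for c in ("proboscis_mm", "corolla_mm"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if (df["proboscis_mm"] <= 0).any():
        raise ValueError("proboscis_mm must be > 0 where present")
    if (df["corolla_mm"] < 0).any():
        raise ValueError("corolla_mm must be >= 0 where present")
    return df


def code_complexity(
    df: pd.DataFrame, deep_threshold_mm: float = DEEP_THRESHOLD_MM
) -> pd.DataFrame:
    """Add the two complexity codes.

    ``is_bilateral`` flags bilateral symmetry; ``is_deep`` flags corolla
    tubes strictly longer than the threshold (a tube of exactly 3.0 mm is
    shallow).  ``is_deep`` is NA where corolla length is missing.
    """
    out = df.copy()
    out["is_bilateral"] = (out["symmetry"] == "bilateral").astype(float)
    out["is_deep"] = (out["corolla_mm"] > deep_threshold_mm).astype(float)
    out.loc[out["corolla_mm"].isna(), "is_deep"] = np.nan
    return out


def complexity_counts(df: pd.DataFrame) -> pd.Series:
    """Visit counts by flower symmetry class; classes partition the total."""
    counts = df["symmetry"].value_counts()
    return pd.Series(
        {"radial": int(counts.get("radial", 0)),
         "bilateral": int(counts.get("bilateral", 0))},
        name="visits",
    )


def _trait_column(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in ("bilateral", "deep"):
        raise ValueError(f"trait must be 'bilateral' or 'deep', got {trait!r}")
    coded = df if f"is_{trait}" in df.columns else code_complexity(df)
    sub = coded.dropna(subset=[f"is_{trait}"])
    return sub, f"is_{trait}"


def per_species_proportions(df: pd.DataFrame, trait: str = "bilateral"):
    """Per-species visit proportions to a complex class, summarized by sociality.

    Returns ``(species, groups)``: one proportion per bee species (species
    with no scorable visits are excluded), then the unweighted mean across
    species per sociality group with both the sample (``ddof=1``) and
    population (``ddof=0``) standard-error conventions.  The s.e. is NA for
    single-species groups.
    """
    sub, col = _trait_column(df, trait)
    species = (
        sub.groupby(["bee_species", "sociality"], observed=True)[col]
        .agg(n_visits="count", proportion="mean")
        .reset_index()
    )
    groups = (
        species.groupby("sociality", observed=True)["proportion"]
        .agg(
            n_species="count",
            mean="mean",
            se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
            se_pop=lambda x: x.std(ddof=0) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        )
        .reset_index()
    )
    return species, groups


def group_mean_corolla(df: pd.DataFrame):
    """Mean +/- s.e. corolla depth of visited flowers, by sociality.

    Computes both conventions: species-level (one mean tube length per bee
    species, then the unweighted mean and s.e. across species) and
    visit-weighted (plain mean and s.e. over rows).
    """
    sub = df.dropna(subset=["corolla_mm"])
    species = (
        sub.groupby(["bee_species", "sociality"], observed=True)["corolla_mm"]
        .agg(n_visits="count", mean_corolla_mm="mean")
        .reset_index()
    )
    rows = []
    for soc, grp in species.groupby("sociality", observed=True):
        visits = sub.loc[sub["sociality"] == soc, "corolla_mm"]
        x = grp["mean_corolla_mm"]
        rows.append(
            {
                "sociality": soc,
                "n_species": len(grp),
                "species_mean_mm": x.mean(),
                "species_se_mm": x.std(ddof=1) / np.sqrt(len(x))
                if len(x) > 1 else 0.0,
                "visit_mean_mm": visits.mean(),
                "visit_se_mm": visits.std(ddof=1) / np.sqrt(len(visits))
                if len(visits) > 1 else 0.0,
            }
        )
    return species, pd.DataFrame(rows)


def size_class_summary(
    df: pd.DataFrame, bins=PROBOSCIS_BINS
) -> pd.DataFrame:
    """Visit shares by proboscis-length class.

    For each flower class (radial, bilateral, and deep/shallow where corolla
    data exist), the share of that class's visits contributed by bees in
    each proboscis bin; shares within a flower class sum to 1.  The last bin
    is closed on the right so a 12 mm proboscis falls in the 9-12 mm class.
    """
    coded = df if "is_bilateral" in df.columns else code_complexity(df)
    sub = coded.dropna(subset=["proboscis_mm"]).copy()
    labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(bins[:-1], bins[1:])]
    sub["size_class"] = pd.cut(
        sub["proboscis_mm"], bins=bins, labels=labels, include_lowest=True
    )
    out = pd.DataFrame(index=pd.CategoricalIndex(labels, name="size_class"))
    classes = {
        "radial": sub["is_bilateral"] == 0,
        "bilateral": sub["is_bilateral"] == 1,
        "shallow": sub["is_deep"] == 0,
        "deep": sub["is_deep"] == 1,
    }
    for name, mask in classes.items():
        total = int(mask.sum())
        counts = sub.loc[mask, "size_class"].value_counts().reindex(labels)
        out[f"share_of_{name}_visits"] = counts / total if total else np.nan
    return out.reset_index()


def fit_choice_regression(
    df: pd.DataFrame, response: str = "bilateral"
) -> pd.DataFrame:
    """ML logistic regression of flower complexity on bee traits.

    Model: ``P(complex) = logit^-1(b0 + b1*eusocial + b2*proboscis_mm +
    b3*eusocial*proboscis_mm)`` fitted to individual visits with no random
    effects — a simplified stand-in for a phylogenetic mixed model whose
    Wald statistics it does not reproduce.  Returns a coefficient table
    (coef, se, z, p); quasi-complete separation is flagged in
    ``result.attrs["separation"]`` rather than raised.
    """
    sub, col = _trait_column(df, response)
    sub = sub.dropna(subset=["proboscis_mm"])
    if sub.empty:
        raise ValueError("no complete rows to fit on")
    y = sub[col].to_numpy()
    eusocial = (sub["sociality"] == "eusocial").to_numpy(dtype=float)
    prob = sub["proboscis_mm"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(prob), eusocial, prob, eusocial * prob])
    names = ["intercept", "eusocial", "proboscis_mm", "eusocial:proboscis_mm"]

    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separation = False
    fit = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                separation = True
        except Exception:  # singular Hessian / separation blow-ups
            separation = True
            try:
                fit = sm.Logit(y, X).fit_regularized(
                    alpha=1e-6, disp=0, maxiter=500)
            except Exception:  # rank-deficient design (constant predictor)
                fit = None
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            separation = True

    if fit is None:
        coefs = np.full(len(names), np.nan)
        se = np.full(len(names), np.nan)
    else:
        coefs = np.asarray(fit.params, dtype=float)
        try:
            se = np.sqrt(np.diag(fit.cov_params()))
        except Exception:
            separation = True
            se = np.full(len(names), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coefs / se
    from scipy.stats import norm

    table = pd.DataFrame(
        {
            "term": names,
            "coef": coefs,
            "se": se,
            "z": z,
            "p": 2 * norm.sf(np.abs(z)),
        }
    )
    table["direction"] = np.sign(table["coef"])
    table["significant_5pct"] = np.abs(table["z"]) >= 1.959963984540054
    table.attrs["separation"] = separation
    table.attrs["response"] = response
    table.attrs["n_obs"] = int(len(sub))
    return table
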