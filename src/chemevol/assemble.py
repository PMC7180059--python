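"""Cross-experiment assembly of species chemical profiles.

Per-sample compound intensities from multiple experiments are standardized
(dry mass, dilution, internal standard), log(+0.1)-transformed, and combined
with a linear mixed model: experiment as a fixed effect, the species-by-
compound cell as the main random effect, and a species-by-compound-by-
experiment identifier nested within it. The species profile matrix is
``max(0, mu_c + u_sc)`` — negative log-scale values fall below the reliable
detection limit and are floored at zero. Derived summaries (totals, compound
counts, jasmonate inducibility, chemotype labels) are computed from that
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_LONG_COLUMNS = ["species", "experiment", "compound", "y"]


class ConvergenceError(RuntimeError):
    """The REML fit failed to converge within the iteration cap."""


# --------------------------------------------------------------------------
# standardization and transform
# --------------------------------------------------------------------------


def standardize(raw_samples: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw ion counts by dry mass, dilution, internal standard.

    Expects long-format rows with at least ``intensity`` and ``dry_mass``;
    optional ``dilution`` (default 1) and ``internal_std`` correction factor
    (default 1; NaN treated as absent). ``dry_mass`` entries may be
    sequences for pooled samples, in which case the mean contributor mass is
    the divisor. Returns a copy with the ``intensity`` column replaced by
    ``intensity / (dry_mass * dilution) * internal_std``.
    """
    if "intensity" not in raw_samples or "dry_mass" not in raw_samples:
        raise ValueError("need 'intensity' and 'dry_mass' columns")
    out = raw_samples.copy()

    def effective_mass(m):
        if isinstance(m, (list, tuple, np.ndarray)):
            m = float(np.mean(m))
        return float(m)

    mass = out["dry_mass"].map(effective_mass)
    if (mass <= 0).any():
        raise ValueError("dry mass must be positive")
    dilution = (
        out["dilution"].fillna(1.0) if "dilution" in out else pd.Series(1.0, out.index)
    )
    if (dilution <= 0).any():
        raise ValueError("dilution factors must be positive")
    istd = (
        out["internal_std"].fillna(1.0)
        if "internal_std" in out
        else pd.Series(1.0, out.index)
    )
    if (istd <= 0).any():
        raise ValueError("internal-standard factors must be positive")
    out["intensity"] = out["intensity"] / (mass * dilution) * istd
    return out


def log_transform(x):
    """The log(+0.1) transform: natural log of x + 0.1, for x >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log(+0.1) transform requires non-negative input")
    out = np.log(arr + 0.1)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


# --------------------------------------------------------------------------
# combining mixed model
# --------------------------------------------------------------------------


@dataclass
class CombiningModelFit:
    """REML fit combining experiments into species-by-compound means."""

    mu: pd.Series  # per-compound mean at the reference experiment
    beta: pd.Series  # experiment fixed effects, reference level = 0
    u: pd.DataFrame  # species x compound BLUPs of the main random effect
    sigma2_u: float
    sigma2_w: float
    sigma2_eps: float
    method: str  # "reml" | "cell_means"
    n_experiments: int
    converged: bool = True
    notes: str = ""


MAX_REML_ITER = 200


def fit_combining_model(
    long_table: pd.DataFrame, response: str = "y"
) -> CombiningModelFit:
    """Fit the experiment-combining mixed model by REML.

    ``long_table`` holds one row per replicate measurement with columns
    ``species, experiment, compound`` and the log-scale response. With a
    single experiment the model is unidentifiable and the fit falls back to
    per-cell means (variance components NaN). If REML fails to converge
    within the iteration cap, or the data are degenerate (e.g. noiseless),
    the same closed-form balanced-design fallback is used and flagged.
    """
    for col in ("species", "experiment", "compound"):
        if col not in long_table:
            raise ValueError(f"long table is missing column {col!r}")
    if response not in long_table:
        raise ValueError(f"long table is missing the response column {response!r}")
    data = long_table.copy()
    data["_cell"] = data["species"].astype(str) + "||" + data["compound"].astype(str)
    experiments = sorted(data["experiment"].unique())

    if len(experiments) < 2:
        fit = _cell_means_fit(data, response, experiments)
        fit.notes = "single experiment: variance components unidentifiable"
        return fit

    # in the noiseless limit the additive cell-means solution fits exactly
    # and is the REML/ML solution (BLUP shrinkage -> 1); REML iterations are
    # numerically unreliable there
    fb = _cell_means_fit(data, response, experiments)
    fitted = (
        data["compound"].map(fb.mu).to_numpy()
        + data["experiment"].map(fb.beta).to_numpy()
        + pd.MultiIndex.from_frame(data[["species", "compound"]])
        .map(fb.u.stack())
        .to_numpy()
    )
    if np.nanmax(np.abs(data[response].to_numpy() - fitted)) < 1e-10:
        fb.sigma2_w = 0.0
        fb.sigma2_eps = 0.0
        fb.notes = "noiseless data: exact additive cell-means solution"
        return fb

    try:
        return _reml_fit(data, response, experiments)
    except (np.linalg.LinAlgError, ValueError, ConvergenceError) as exc:
        fit = _cell_means_fit(data, response, experiments)
        fit.converged = False
        fit.notes = f"REML failed ({exc}); balanced cell-means fallback"
        return fit


def _reml_fit(data, response, experiments) -> CombiningModelFit:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(columns={response: "_y"})
    resid_scale = float(np.var(df["_y"]))
    if resid_scale < 1e-12:
        raise ConvergenceError("response has (near-)zero variance")

    model = smf.mixedlm(
        "_y ~ C(experiment) + C(compound) + 0",
        data=df,
        groups=df["_cell"],
        re_formula="1",
        vc_formula={"cellexp": "0 + C(experiment)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, maxiter=MAX_REML_ITER, method=["lbfgs"])
    if not result.converged:
        raise ConvergenceError(f"REML did not converge in {MAX_REML_ITER} iterations")

    params = result.params
    compounds = sorted(df["compound"].unique())
    # with "~ C(experiment) + C(compound) + 0" patsy expands experiment fully
    # and compound with its first level as reference
    exp_coefs = {}
    for e in experiments:
        key = f"C(experiment)[{e}]"
        exp_coefs[e] = float(params[key]) if key in params.index else 0.0
    ref = experiments[0]
    beta = pd.Series(
        {e: exp_coefs[e] - exp_coefs[ref] for e in experiments}, name="beta"
    )
    mu = {}
    for c in compounds:
        key = f"C(compound)[T.{c}]"
        mu[c] = exp_coefs[ref] + (float(params[key]) if key in params.index else 0.0)
    mu = pd.Series(mu, name="mu")

    species = sorted(df["species"].unique())
    u = pd.DataFrame(0.0, index=species, columns=compounds)
    for cell, re_vals in result.random_effects.items():
        sp, comp = cell.split("||", 1)
        u.loc[sp, comp] = float(re_vals.iloc[0])  # the cell intercept BLUP

    sigma2_u = float(result.cov_re.iloc[0, 0])
    vcomp = result.vcomp
    sigma2_w = float(vcomp[0]) if len(vcomp) else float("nan")
    sigma2_eps = float(result.scale)
    return CombiningModelFit(
        mu=mu,
        beta=beta,
        u=u,
        sigma2_u=sigma2_u,
        sigma2_w=sigma2_w,
        sigma2_eps=sigma2_eps,
        method="reml",
        n_experiments=len(experiments),
    )


def _cell_means_fit(data, response, experiments) -> CombiningModelFit:
    """Closed-form fallback: experiment offsets from experiment means,
    cell effects from offset-corrected cell means. Exact in the noiseless
    limit and for a single experiment."""
    df = data
    ref = experiments[0]
    exp_means = df.groupby("experiment")[response].mean()
    beta = pd.Series(
        {e: float(exp_means[e] - exp_means[ref]) for e in experiments}, name="beta"
    )
    corrected = df[response] - df["experiment"].map(beta)
    cells = (
        pd.DataFrame(
            {"species": df["species"], "compound": df["compound"], "v": corrected}
        )
        .groupby(["species", "compound"])["v"]
        .mean()
        .unstack("compound")
    )
    mu = cells.mean(axis=0)
    u = cells.sub(mu, axis=1)
    mu.name, u.index.name = "mu", None
    return CombiningModelFit(
        mu=mu,
        beta=beta,
        u=u,
        sigma2_u=float("nan"),
        sigma2_w=float("nan"),
        sigma2_eps=float("nan"),
        method="cell_means",
        n_experiments=len(experiments),
    )


# --------------------------------------------------------------------------
# species profile matrix and summaries
# --------------------------------------------------------------------------


@dataclass
class SpeciesProfileMatrix:
    """Species x compound log-scale means with companion summaries."""

    matrix: pd.DataFrame  # floored log-scale means
    totals: pd.Series  # row sums after back-transform (intensity scale)
    totals_log: pd.Series  # row sums of the floored log-scale matrix
    counts: pd.Series  # per-species number of nonzero compounds


def extract_species_means(fit: CombiningModelFit) -> SpeciesProfileMatrix:
    """Species profile matrix ``max(0, mu_c + u_sc)`` plus summaries.

    Negative log-scale values correspond to intensities below the reliable
    detection limit and are set to zero. ``totals`` back-transforms each
    positive entry (exp(m) - 0.1) before summing; ``counts`` is the number
    of entries above zero per species.
    """
    matrix = fit.u.add(fit.mu, axis=1).clip(lower=0.0)
    back = np.maximum(np.exp(matrix) - 0.1, 0.0)
    back[matrix <= 0] = 0.0
    totals = back.sum(axis=1)
    return SpeciesProfileMatrix(
        matrix=matrix,
        totals=totals,
        totals_log=matrix.sum(axis=1),
        counts=(matrix > 0).sum(axis=1),
    )


@dataclass
class InducibilityResult:
    """Per-species JA-minus-control differences and their grand mean CI."""

    delta: pd.Series
    mean: float
    ci: tuple
    significant: Optional[bool]
    notes: str = ""


def compute_inducibility(control_totals, ja_totals, conf=0.95) -> InducibilityResult:
    """JA inducibility: per-species total differences with a t-based CI.

    Accepts per-species totals (Series) or :class:`SpeciesProfileMatrix`
    instances. The grand mean difference carries a t-based confidence
    interval; non-overlap with zero flags a significant across-species
    effect.
    """
    if isinstance(control_totals, SpeciesProfileMatrix):
        control_totals = control_totals.totals
    if isinstance(ja_totals, SpeciesProfileMatrix):
        ja_totals = ja_totals.totals
    shared = control_totals.index.intersection(ja_totals.index)
    if len(shared) == 0:
        raise ValueError("no shared species between treatment groups")
    delta = (ja_totals[shared] - control_totals[shared]).rename("delta")
    n = len(delta)
    mean = float(delta.mean())
    if n < 2:
        return InducibilityResult(
            delta=delta,
            mean=mean,
            ci=(float("nan"), float("nan")),
            significant=None,
            notes="single species: confidence interval undefined",
        )
    se = float(delta.std(ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(0.5 + conf / 2, df=n - 1)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return InducibilityResult(
        delta=delta, mean=mean, ci=ci, significant=not (ci[0] <= 0.0 <= ci[1])
    )


@dataclass
class ChemotypeRules:
    """Compound-to-class map with a deterministic tie-break priority."""

    class_map: dict  # compound id -> class label
    priority: tuple = ()  # tie-break order; unlisted classes sort alphabetically


def classify_chemotype(profile_matrix: pd.DataFrame, rules: ChemotypeRules):
    """Label each species by its dominant compound class.

    Class scores are summed matrix intensities; the label is the class with
    the largest summed share. Ties break deterministically by the rules'
    priority order (then alphabetically) and are flagged. Returns
    ``(labels, tied)`` Series.
    """
    if isinstance(profile_matrix, SpeciesProfileMatrix):
        profile_matrix = profile_matrix.matrix
    missing = [c for c in profile_matrix.columns if c not in rules.class_map]
    if missing:
        raise ValueError(f"compounds missing from the class map: {missing}")

    def rank(cls):
        if cls in rules.priority:
            return (0, rules.priority.index(cls))
        return (1, cls)

    labels, tied = {}, {}
    by_class = profile_matrix.T.groupby(
        profile_matrix.columns.map(rules.class_map)
    ).sum().T
    for sp, row in by_class.iterrows():
        best = row.max()
        winners = sorted(row.index[row == best], key=rank)
        labels[sp] = winners[0]
        tied[sp] = len(winners) > 1
    return pd.Series(labels, name="chemotype"), pd.Series(tied, name="tied")
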