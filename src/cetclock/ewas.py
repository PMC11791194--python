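"""Two-step Stouffer meta-analysis EWAS of age and sex across strata.

Samples are stratified by species and tissue; a stratum enters the analysis
only when its sample size is >= ``min_n`` (15 by default). Within a stratum
the age EWAS is a per-CpG Pearson correlation with chronological age; the
sex EWAS is a per-CpG ordinary least squares fit of beta on a female
indicator adjusted for age (Female = 1, Male = 0; unknown sex excluded).
Each per-CpG statistic is converted to a signed z-score via the two-sided
p-value of its t statistic, with all tail probabilities kept in natural-log
space so meta-analysis p-values far below the double-precision underflow
limit (the interesting CpGs reach ~1e-115) remain exact.

Meta-analysis combines signed z-scores with the unweighted Stouffer method,
``z_meta = sum(z_i) / sqrt(k)``. For the all-tissue age analysis and the sex
analysis the combination is two-step: tissue strata are first combined
within species, then the species-level z-scores are combined across
species. Tissue-restricted age analyses combine that tissue's species
strata in a single step. A CpG whose statistic is unavailable in a stratum
(zero variance, skipped stratum) simply reduces k for that CpG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import BetaMatrix, SamplePanel, ValidationError

logger = logging.getLogger(__name__)

LOG2 = float(np.log(2.0))

ANALYSES = ("age-all", "age-blood", "age-skin", "sex")


@dataclass
class StratumEWAS:
    """Per-CpG association statistics for one species x tissue stratum."""

    species: str
    tissue: str
    n: int
    kind: str  # "age" | "sex"
    table: pd.DataFrame  # cpg_id, stat, t, log_p, z (NaN where unavailable)


@dataclass
class MetaEWAS:
    """Stouffer-combined per-CpG statistics for one analysis."""

    analysis: str
    table: pd.DataFrame  # cpg_id, meta_z, log_p, k, direction
    n_strata: int

    def significant(self, log_threshold: float) -> pd.DataFrame:
        """Rows with natural-log p below ``log_threshold``."""
        return self.table[self.table["log_p"] < log_threshold]


def _z_from_t(t: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed normal z and two-sided log-p from t statistics, in log space.

    |z| solves 2*Phi(-|z|) = p with p/2 = Student-t upper tail of |t|;
    computed via the log-quantile ``ndtri_exp`` so |t| of hundreds maps to
    finite z instead of saturating at the float underflow of p.
    """
    with np.errstate(invalid="ignore"):
        log_half_p = stats.t.logsf(np.abs(t), df)
    # scipy's t tail underflows to -inf at large df; fall back to the
    # moment-matched normal deviate (Fisher approximation), accurate there
    bad = np.isneginf(log_half_p) & np.isfinite(np.asarray(t, dtype=float))
    if np.any(bad):
        tt = np.abs(np.asarray(t, dtype=float))[bad]
        dd = np.broadcast_to(np.asarray(df, dtype=float), np.shape(t))[bad]
        z_eq = tt * (1 - 1 / (4 * dd)) / np.sqrt(1 + tt**2 / (2 * dd))
        log_half_p = np.asarray(log_half_p)
        log_half_p[bad] = stats.norm.logsf(z_eq)
    log_p = LOG2 + log_half_p
    absz = -special.ndtri_exp(log_half_p)
    return np.sign(t) * absz, log_p


def _nan_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r of X against y, pairwise-complete per column."""
    n_obs = np.full(X.shape[1], len(y), dtype=float)
    if np.isnan(X).any():
        r = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = ~np.isnan(col)
            n_obs[j] = ok.sum()
            if n_obs[j] < 3 or np.std(col[ok]) == 0 or np.std(y[ok]) == 0:
                r[j] = np.nan
            else:
                r[j] = np.corrcoef(col[ok], y[ok])[0, 1]
        return r, n_obs
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return r, n_obs


def stratum_age_ewas(
    betas: BetaMatrix, panel: SamplePanel, min_n: int = 15
) -> StratumEWAS | None:
    """Pearson-correlation EWAS of age in one species x tissue stratum.

    Returns None (with a logged notice) when the stratum is smaller than
    ``min_n``. Zero-variance CpGs carry NaN statistics.
    """
    strata = panel.strata()
    if len(strata) != 1:
        raise ValidationError(f"expected a single stratum, got {strata}")
    species, tissue = strata[0]
    n = len(panel)
    if n < min_n:
        logger.info("stratum (%s, %s) skipped: n=%d < %d", species, tissue, n, min_n)
        return None
    y = np.asarray(panel.age_years, dtype=float)
    if np.std(y) == 0:
        logger.info("stratum (%s, %s) skipped: constant age", species, tissue)
        return None
    r, n_obs = _nan_pearson(betas.values, y)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    dof = n_obs - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof) / np.sqrt(1 - r**2)
    z, log_p = _z_from_t(t, dof)
    return StratumEWAS(
        species=species,
        tissue=tissue,
        n=n,
        kind="age",
        table=pd.DataFrame(
            {"cpg_id": betas.cpg_ids, "stat": r, "t": t, "log_p": log_p, "z": z}
        ),
    )


def stratum_sex_ewas(
    betas: BetaMatrix, panel: SamplePanel, min_n: int = 15
) -> StratumEWAS | None:
    """Age-adjusted OLS EWAS of sex: beta ~ female + age, per CpG.

    The reported statistic is the female-coefficient estimate with its t
    (df = n - 3) and signed z. Strata with a single sex, constant age, or a
    rank-deficient design are skipped with a diagnostic.
    """
    strata = panel.strata()
    if len(strata) != 1:
        raise ValidationError(f"expected a single stratum, got {strata}")
    species, tissue = strata[0]
    known = np.asarray([s in ("F", "M") for s in panel.sex])
    if not known.all():
        panel = panel.subset(known)
        betas = betas.subset_samples(known)
    n = len(panel)
    if n < min_n:
        logger.info("stratum (%s, %s) skipped: n=%d < %d", species, tissue, n, min_n)
        return None
    female = np.asarray([1.0 if s == "F" else 0.0 for s in panel.sex])
    age = np.asarray(panel.age_years, dtype=float)
    if len(set(female)) < 2:
        logger.info("stratum (%s, %s) skipped: single-sex", species, tissue)
        return None
    if np.std(age) == 0:
        logger.info("stratum (%s, %s) skipped: constant age", species, tissue)
        return None
    D = np.column_stack([np.ones(n), female, age])
    if np.linalg.matrix_rank(D) < 3:
        logger.info("stratum (%s, %s) skipped: rank-deficient design", species, tissue)
        return None

    DtD_inv = np.linalg.inv(D.T @ D)
    X = betas.values
    nan_cols = np.isnan(X).any(axis=0)
    coef = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    full = ~nan_cols
    if full.any():
        B = DtD_inv @ D.T @ X[:, full]  # 3 x p
        resid = X[:, full] - D @ B
        dof = n - 3
        sigma2 = (resid**2).sum(axis=0) / dof
        coef[full] = B[1]
        se[full] = np.sqrt(sigma2 * DtD_inv[1, 1])
    for j in np.nonzero(nan_cols)[0]:
        ok = ~np.isnan(X[:, j])
        if ok.sum() < 4:
            continue
        Dj = D[ok]
        if np.linalg.matrix_rank(Dj) < 3:
            continue
        Gj = np.linalg.inv(Dj.T @ Dj)
        Bj = Gj @ Dj.T @ X[ok, j]
        rj = X[ok, j] - Dj @ Bj
        s2 = (rj**2).sum() / (ok.sum() - 3)
        coef[j], se[j] = Bj[1], np.sqrt(s2 * Gj[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    t[np.isinf(t)] = np.nan
    z, log_p = _z_from_t(t, n - 3)
    return StratumEWAS(
        species=species,
        tissue=tissue,
        n=n,
        kind="sex",
        table=pd.DataFrame(
            {"cpg_id": betas.cpg_ids, "stat": coef, "t": t, "log_p": log_p, "z": z}
        ),
    )


def run_strata(
    betas: BetaMatrix, panel: SamplePanel, kind: str = "age", min_n: int = 15
) -> list[StratumEWAS]:
    """Run the per-stratum EWAS over every species x tissue stratum."""
    out: list[StratumEWAS] = []
    fn = stratum_age_ewas if kind == "age" else stratum_sex_ewas
    for species, tissue in panel.strata():
        mask = np.asarray(
            [s == species and t == tissue for s, t in zip(panel.species, panel.tissue)]
        )
        res = fn(betas.subset_samples(mask), panel.subset(mask), min_n=min_n)
        if res is not None:
            out.append(res)
    return out


def stouffer_combine(z_values) -> tuple[float, float]:
    """Unweighted Stouffer combination: z = sum(z_i)/sqrt(k).

    Returns (meta z, two-sided log-space p).
    """
    z = np.asarray(list(z_values), dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValidationError("cannot combine an empty list of z-scores")
    meta_z = float(z.sum() / np.sqrt(z.size))
    log_p = float(LOG2 + stats.norm.logsf(abs(meta_z)))
    return meta_z, log_p


def _stouffer_rows(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unweighted Stouffer over a (cpgs x strata) matrix with NaNs."""
    avail = np.isfinite(Z)
    k = avail.sum(axis=1)
    s = np.where(avail, Z, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta = s / np.sqrt(k)
    meta[k == 0] = np.nan
    return meta, k


def two_step_meta(strata: list[StratumEWAS], analysis: str) -> MetaEWAS:
    """Combine stratum z-scores into a meta-analysis for ``analysis``.

    ``age-all`` and ``sex``: two-step (tissues within species, then across
    species). ``age-blood`` / ``age-skin``: single-step across that tissue's
    species strata. A species with a single eligible tissue passes its z
    through step 1 unchanged.
    """
    if analysis not in ANALYSES:
        raise ValidationError(f"unknown analysis {analysis!r}")
    if analysis in ("age-blood", "age-skin"):
        tissue = analysis.split("-")[1]
        strata = [s for s in strata if s.tissue == tissue]
    if not strata:
        raise ValidationError(f"no eligible strata for analysis {analysis!r}")

    z_cols = {}
    for s in strata:
        z_cols[f"{s.species}|{s.tissue}"] = s.table.set_index("cpg_id")["z"]
    Z = pd.DataFrame(z_cols)  # union of CpGs, NaN where absent

    if analysis in ("age-all", "sex"):
        by_species: dict[str, list[str]] = {}
        for key in Z.columns:
            by_species.setdefault(key.split("|")[0], []).append(key)
        species_z = {}
        k_total = np.zeros(len(Z), dtype=int)
        for sp, cols in by_species.items():
            mz, k = _stouffer_rows(Z[cols].to_numpy())
            species_z[sp] = mz
            k_total += k
        S = pd.DataFrame(species_z, index=Z.index)
        meta_z, _ = _stouffer_rows(S.to_numpy())
        k = k_total
    else:
        meta_z, k = _stouffer_rows(Z.to_numpy())

    with np.errstate(invalid="ignore"):
        log_p = LOG2 + stats.norm.logsf(np.abs(meta_z))
    table = pd.DataFrame(
        {
            "cpg_id": Z.index,
            "meta_z": meta_z,
            "log_p": log_p,
            "k": k,
            "direction": np.where(meta_z >= 0, "+", "-"),
        }
    )
    table = table[table["k"] > 0].reset_index(drop=True)
    return MetaEWAS(analysis=analysis, table=table, n_strata=len(strata))


def select_top(meta: MetaEWAS, n: int = 1000, direction: str = "positive") -> list[str]:
    """Top-n CpG ids of the requested sign, ordered by |meta z| descending.

    Ties break by (log p ascending, cpg_id lexicographic). If fewer than
    ``n`` CpGs carry the requested sign, all of them are returned with a
    warning.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError("direction must be 'positive' or 'negative'")
    t = meta.table.dropna(subset=["meta_z"])
    t = t[t["meta_z"] > 0] if direction == "positive" else t[t["meta_z"] < 0]
    if len(t) < n:
        logger.warning(
            "only %d %s-z CpGs available (requested %d)", len(t), direction, n
        )
    t = t.assign(absz=t["meta_z"].abs()).sort_values(
        ["absz", "log_p", "cpg_id"], ascending=[False, True, True], kind="mergesort"
    )
    return t["cpg_id"].head(n).tolist()


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests
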