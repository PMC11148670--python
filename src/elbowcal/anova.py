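"""Within-subject ANOVA and generalized eta squared for calibration studies.

The study design is fully within-subject: every subject contributes a
repetition-averaged accuracy value for each calibration x joint-axis x task
cell. For a balanced complete design the sums of squares decompose exactly by
marginal means; each within effect is tested against its own subject-by-effect
error stratum. Generalized eta squared pools, per Bakeman's formulation for
fully repeated-measures designs, the subject variance and *all* error strata
into the denominator:

    ges(effect) = SS_effect / (SS_effect + SS_subjects + sum of all error SS)

Sphericity is assessed per effect with Mauchly's test on the
contrast-projected covariance; when violated (p < .05) the Greenhouse-Geisser
epsilon rescales both degrees of freedom before the p-value is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "generalized_eta_squared",
    "rm_anova",
    "rm_anova_three_way",
    "effects_to_frame",
    "IncompleteDesignError",
]

SPHERICITY_ALPHA = 0.05


class IncompleteDesignError(ValueError):
    """The subject x factor design has empty cells."""


@dataclass
class AnovaEffect:
    effect_name: str
    df_numerator: float
    df_denominator: float
    F: float
    p: float
    ges: float
    epsilon: float = 1.0
    mauchly_p: float = np.nan
    sphericity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if not 0.0 <= self.ges <= 1.0:
            raise ValueError("ges must lie in [0, 1]")


def generalized_eta_squared(ss_effect: float, ss_subject_and_error_terms) -> float:
    """``ss_effect / (ss_effect + sum(subject and error sums of squares))``."""
    terms = np.asarray(list(ss_subject_and_error_terms), dtype=float)
    if ss_effect < 0 or np.any(terms < 0):
        raise ValueError("sums of squares must be non-negative")
    denom = ss_effect + terms.sum()
    if denom <= 0:
        raise ValueError("all-zero sums of squares: effect size undefined")
    return float(ss_effect / denom)


def _cell_array(
    df: pd.DataFrame, dv: str, subject: str, within: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, list]]:
    levels = {subject: sorted(df[subject].unique())}
    for f in within:
        levels[f] = sorted(df[f].unique())
    grouped = df.groupby([subject, *within], observed=True)[dv].mean()
    full_index = pd.MultiIndex.from_product(
        [levels[subject]] + [levels[f] for f in within], names=[subject, *within]
    )
    aligned = grouped.reindex(full_index)
    if aligned.isna().any():
        missing = aligned[aligned.isna()].index.tolist()[:10]
        raise IncompleteDesignError(
            f"{int(aligned.isna().sum())} empty design cells, e.g. {missing}"
        )
    shape = [len(levels[subject])] + [len(levels[f]) for f in within]
    return aligned.to_numpy().reshape(shape), levels

def _effect_ss(y: np.ndarray, dims: tuple[int, ...]) -> float:
    """Balanced-design sum of squares of the effect spanned by ``dims``."""
    total_dims = tuple(range(y.ndim))
    effect = np.zeros([y.shape[d] if d in dims else 1 for d in total_dims])
    for sub_size in range(len(dims) + 1):
        for sub in combinations(dims, sub_size):
            reduce_over = tuple(d for d in total_dims if d not in sub)
            m = y.mean(axis=reduce_over, keepdims=True)
            effect = effect + ((-1) ** (len(dims) - len(sub))) * m
    excluded = int(np.prod([y.shape[d] for d in total_dims if d not in dims]))
    return float(excluded * np.sum(effect**2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    basis = np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:]


def _sphericity(y: np.ndarray, factor_dims: tuple[int, ...]) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p for one within effect.

    ``y`` is the subject x factors cell array; factors not in the effect are
    averaged out, the rest are projected onto the effect's orthonormal
    contrast space (Kronecker product across the effect's factors).
    """
    n_sub = y.shape[0]
    other = tuple(d for d in range(1, y.ndim) if d not in factor_dims)
    collapsed = y.mean(axis=other) if other else y
    x = collapsed.reshape(n_sub, -1)
    c = np.array([[1.0]])
    for d in sorted(factor_dims):
        c = np.kron(c, _orthonormal_contrasts(y.shape[d]))
    proj = x @ c
    df = proj.shape[1]
    if df <= 1:
        return 1.0, 1.0  # a single contrast is trivially spherical
    s = np.cov(proj, rowvar=False, ddof=1)
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0 or tr <= 0:
        return 1.0, 1.0
    eps = float(tr**2 / (df * tr2))
    eps = min(1.0, max(eps, 1.0 / df))
    det = np.linalg.det(s)
    if det <= 0 or n_sub - 1 <= df:
        return eps, 0.0  # singular covariance: treat sphericity as violated
    w = det / (tr / df) ** df
    d_corr = 1.0 - (2.0 * df**2 + df + 2.0) / (6.0 * df * (n_sub - 1))
    chi2 = -(n_sub - 1) * d_corr * np.log(w)
    dof = df * (df + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, dof))
    return eps, p


def rm_anova(
    df: pd.DataFrame, dv: str, subject: str = "subject", within: tuple[str, ...] = ()
) -> list[AnovaEffect]:
    """Fully within-subject ANOVA over a balanced complete design.

    Rows sharing a subject x cell combination (repetitions) are averaged
    first. Returns one :class:`AnovaEffect` per within effect (main effects
    and all interactions), with Greenhouse-Geisser-corrected degrees of
    freedom whenever Mauchly's test rejects sphericity.
    """
    if not within:
        raise ValueError("at least one within factor is required")
    y, _levels = _cell_array(df, dv, subject, tuple(within))
    factor_dims = tuple(range(1, y.ndim))
    ss = {}
    for r in range(1, len(factor_dims) + 1):
        for sub in combinations(factor_dims, r):
            ss[sub] = _effect_ss(y, sub)  # within effect
            ss[(0, *sub)] = _effect_ss(y, (0, *sub))  # its error stratum
    ss_subject = _effect_ss(y, (0,))
    pooled_noise = ss_subject + sum(ss[(0, *sub)] for sub in _all_subsets(factor_dims))

    effects = []
    for sub in _all_subsets(factor_dims):
        name = " * ".join(f"f{d}" for d in sub)
        df_num = float(np.prod([y.shape[d] - 1 for d in sub]))
        df_den = float((y.shape[0] - 1) * df_num)
        ss_eff = ss[sub]
        ss_err = ss[(0, *sub)]
        if ss_err <= 1e-12 * max(1.0, abs(ss_eff)):
            f_val = 0.0 if ss_eff <= 1e-12 else np.inf
            p = 1.0 if f_val == 0.0 else 0.0
            eps, mauchly_p, corrected = 1.0, np.nan, False
        else:
            f_val = (ss_eff / df_num) / (ss_err / df_den)
            eps, mauchly_p = _sphericity(y, sub)
            corrected = mauchly_p < SPHERICITY_ALPHA and df_num > 1
            if corrected:
                df_num *= eps
                df_den *= eps
            p = float(sps.f.sf(f_val, df_num, df_den))
        # effects below numerical resolution (micro-degree excursions) are
        # reported as zero rather than as a ratio of rounding noise
        denom = ss_eff + pooled_noise
        if ss_eff < 1e-12 or denom <= 0:
            ges = 0.0
        else:
            ges = generalized_eta_squared(ss_eff, [pooled_noise])
        effects.append(
            AnovaEffect(
                effect_name=name,
                df_numerator=df_num,
                df_denominator=df_den,
                F=float(f_val) if np.isfinite(f_val) else 0.0,
                p=p,
                ges=ges,
                epsilon=eps,
                mauchly_p=mauchly_p,
                sphericity_corrected=corrected,
            )
        )
    # rename effects with the real factor labels
    names = {f"f{d}": within[d - 1] for d in factor_dims}
    for e in effects:
        e.effect_name = " * ".join(names[tok] for tok in e.effect_name.split(" * "))
    return effects


def _all_subsets(dims: tuple[int, ...]):
    return chain.from_iterable(combinations(dims, r) for r in range(1, len(dims) + 1))


DV_COLUMNS = {"rom_error": "rom_error_deg", "rmse": "rmse_deg", "offset": "offset_deg"}


def rm_anova_three_way(records: pd.DataFrame, dv: str) -> list[AnovaEffect]:
    """Three-way calibration x axis x task within-subject ANOVA on a metric table.

    ``records`` is the tidy table from :func:`elbowcal.metrics.records_to_frame`;
    ``dv`` is one of ``rom_error``, ``rmse`` or ``offset``. Repetitions are
    averaged per cell before the decomposition.
    """
    column = DV_COLUMNS.get(dv, dv)
    if column not in records.columns:
        raise KeyError(f"dependent variable column {column!r} not in table")
    return rm_anova(records, column, subject="subject", within=("calibration", "axis", "task"))


def effects_to_frame(effects: list[AnovaEffect]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "effect": e.effect_name,
                "df_num": e.df_numerator,
                "df_den": e.df_denominator,
                "F": e.F,
                "p": e.p,
                "ges": e.ges,
                "gg_epsilon": e.epsilon,
                "mauchly_p": e.mauchly_p,
                "gg_applied": e.sphericity_corrected,
            }
        )
    return pd.DataFrame(rows)
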