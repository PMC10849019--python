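"""Cohort-level inference: correlations, confound correction, PID.

Associations are tested with Spearman rank correlation.  Dependent variables
are corrected for confounds by sequential regression-out: each significant
confound is mean-centred, orthogonalized against the previously removed
ones, and its least-squares projection subtracted from the dependent
variable, so the corrected variable is linearly uncorrelated with every
removed confound.

Partial information decomposition (PID) splits the joint mutual information
of the two motor scores about CKC into unique, redundant and synergistic
parts.  Variables are Gaussian-copula rank normalized, mutual informations
follow from the empirical correlation matrix in closed form, and redundancy
uses the minimum-mutual-information (MMI) lattice for two sources —
``R = min(I(S1;T), I(S2;T))`` — which keeps all four components
non-negative.  Significance comes from permuting the score rows jointly
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

LN2 = float(np.log(2.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t approximation).

    Ties receive average ranks.  Constant inputs are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of at least 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Confound screening and sequential orthogonalized correction
# ---------------------------------------------------------------------------

@dataclass
class CorrectionChain:
    dependent: str
    removed: list[str]
    corrected: np.ndarray
    diagnostics: pd.DataFrame

    @property
    def confounds(self) -> list[str]:
        return self.removed


def screen_and_correct(table: pd.DataFrame, dependent: str,
                       candidate_confounds: list[str],
                       alpha: float = 0.05) -> CorrectionChain:
    """Screen candidate confounds in order and regress out the significant ones.

    For each candidate (in the given order): test its Spearman association
    with the *current* dependent variable; if p < alpha, mean-centre it,
    orthogonalize it against the previously removed confounds, and subtract
    its least-squares projection from the dependent variable.  Candidates
    that become numerically collinear with already-removed confounds are
    skipped with a warning entry in the diagnostics.
    """
    y = table[dependent].to_numpy(dtype=float).copy()
    removed_names: list[str] = []
    basis: list[np.ndarray] = []
    rows = []
    for name in candidate_confounds:
        c = table[name].to_numpy(dtype=float)
        rho, p = spearman(c, y)
        if p >= alpha:
            rows.append({"confound": name, "rho": rho, "p": p, "removed": False,
                         "note": "not significant"})
            continue
        v = c - c.mean()
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        if np.linalg.norm(v) < 1e-10 * max(1.0, np.linalg.norm(c - c.mean())):
            rows.append({"confound": name, "rho": rho, "p": p, "removed": False,
                         "note": "collinear with previously removed confounds"})
            continue
        y = y - (y @ v) / (v @ v) * v
        basis.append(v)
        removed_names.append(name)
        rows.append({"confound": name, "rho": rho, "p": p, "removed": True,
                     "note": ""})
    diagnostics = pd.DataFrame(rows, columns=["confound", "rho", "p", "removed", "note"])
    return CorrectionChain(dependent=dependent, removed=removed_names,
                           corrected=y, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Gaussian-copula PID
# ---------------------------------------------------------------------------

def copula_normalize(column) -> np.ndarray:
    """Gaussian copula rank normalization.

    Average-tie ranks are mapped to uniforms ``r/(n+1)`` and then through the
    standard normal quantile function; the output depends on the input only
    through its ranks.
    """
    x = np.asarray(column, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("copula normalization undefined for a constant column")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf(ranks / (len(x) + 1.0))


def _gaussian_mi(rho: float) -> float:
    """MI (nats) of a bivariate Gaussian with correlation rho."""
    return -0.5 * np.log(max(1e-300, 1.0 - rho * rho))


@dataclass
class PIDResult:
    """MMI partial information decomposition of two sources about a target.

    Components are reported in **bits**.  The lattice identities
    ``unique_i + redundancy = I(S_i;T)`` and
    ``unique1 + unique2 + redundancy + synergy = I(S1,S2;T)`` hold by
    construction.
    """

    unique1: float
    unique2: float
    redundancy: float
    synergy: float
    joint_mi: float
    mi1: float
    mi2: float
    source1: str = "source1"
    source2: str = "source2"
    target: str = "target"
    n_permutations: int = 0
    z_scores: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def components(self) -> dict[str, float]:
        return {"unique1": self.unique1, "unique2": self.unique2,
                "redundancy": self.redundancy, "synergy": self.synergy}


def _pid_from_columns(s1: np.ndarray, s2: np.ndarray, t: np.ndarray) -> np.ndarray:
    """PID components [U1, U2, R, S, joint, mi1, mi2] in bits from
    copula-normalized columns."""
    c = np.corrcoef(np.column_stack([s1, s2, t]), rowvar=False)
    det3 = np.linalg.det(c)
    det_ss = c[0, 0] * c[1, 1] - c[0, 1] ** 2
    mi1 = _gaussian_mi(c[0, 2])
    mi2 = _gaussian_mi(c[1, 2])
    if det_ss <= 1e-12:
        # duplicated sources (|rho12| = 1): the pair carries no more
        # information than either source alone
        joint = max(mi1, mi2)
    elif det3 <= 1e-12:
        raise ValueError("singular correlation matrix; PID undefined "
                         "(a source or the target is a deterministic linear "
                         "combination of the others)")
    else:
        joint = 0.5 * np.log(det_ss / det3)   # I(S1,S2;T), sigma_T = 1
    red = min(mi1, mi2)
    u1 = mi1 - red
    u2 = mi2 - red
    syn = joint - u1 - u2 - red
    return np.array([u1, u2, red, syn, joint, mi1, mi2]) / LN2


def pid_two_sources(table: pd.DataFrame, source1: str, source2: str,
                    target: str, normalize: bool = True) -> PIDResult:
    """Point-estimate Gaussian-copula MMI PID of two sources about a target.

    Columns are copula-normalized (set ``normalize=False`` if already done);
    mutual informations come from the empirical correlation matrix via the
    Gaussian closed forms.
    """
    cols = [table[source1], table[source2], table[target]]
    if len(table) < 10:
        raise ValueError("PID needs at least 10 subjects")
    s1, s2, t = (copula_normalize(c) if normalize else np.asarray(c, float)
                 for c in cols)
    u1, u2, red, syn, joint, mi1, mi2 = _pid_from_columns(s1, s2, t)
    return PIDResult(unique1=u1, unique2=u2, redundancy=red, synergy=syn,
                     joint_mi=joint, mi1=mi1, mi2=mi2,
                     source1=source1, source2=source2, target=target)


def pid_permutation_test(table: pd.DataFrame, source1: str, source2: str,
                         target: str, n_permutations: int = 1000,
                         seed: int | np.random.SeedSequence | None = None,
                         ) -> PIDResult:
    """PID with permutation z-scores and one-sided p-values.

    The two source columns are permuted *jointly* across subjects (the
    target stays fixed), preserving the sources' mutual structure under the
    null of no source-target association.  ``z = (obs - mean) / SD`` over
    permutations; ``p = (1 + #{perm >= obs}) / (n + 1)``.
    """
    import warnings

    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; z-scores will be unstable")
    rng = np.random.default_rng(seed)
    s1 = copula_normalize(table[source1])
    s2 = copula_normalize(table[source2])
    t = copula_normalize(table[target])
    obs = _pid_from_columns(s1, s2, t)
    n = len(t)
    perms = np.empty((n_permutations, 4))
    for i in range(n_permutations):
        idx = rng.permutation(n)
        perms[i] = _pid_from_columns(s1[idx], s2[idx], t)[:4]
    mean = perms.mean(axis=0)
    sd = perms.std(axis=0, ddof=1)
    names = ("unique1", "unique2", "redundancy", "synergy")
    z = {nm: float((obs[k] - mean[k]) / sd[k]) if sd[k] > 0 else np.inf
         for k, nm in enumerate(names)}
    p = {nm: float((1 + np.sum(perms[:, k] >= obs[k])) / (n_permutations + 1))
         for k, nm in enumerate(names)}
    return PIDResult(unique1=obs[0], unique2=obs[1], redundancy=obs[2],
                     synergy=obs[3], joint_mi=obs[4], mi1=obs[5], mi2=obs[6],
                     source1=source1, source2=source2, target=target,
                     n_permutations=n_permutations, z_scores=z, p_values=p)


# ---------------------------------------------------------------------------
# Headline battery
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def headline_analyses(table: pd.DataFrame, alpha: float = 0.05,
                      n_permutations: int = 1000,
                      seed: int | np.random.SeedSequence | None = None) -> dict:
    """The standard cohort battery for a CKC study table.

    Expects columns ``score1`` (gross motor), ``score2`` (fine motor),
    ``ckc_f0``, ``ckc_f1``, ``snr_f0``, ``snr_f1``, ``modulation_depth``,
    the coordination measures and the two regularity side peaks.  Returns a
    dict with: composite columns, confound-correction chains (regularity
    corrected for modulation depth; coordination for modulation depth and
    corrected regularity; CKC for modulation depth, corrected regularity and
    EEG SNR), the Spearman correlation matrix of all headline variables, the
    CKC-vs-score contrast ``z(CKC at F1) - z(score1)`` against ``score2``,
    the PID of the two scores about CKC at F1, and a Wilcoxon signed-rank
    comparison of CKC at F0 vs F1.
    """
    from .emg import combine_standardized

    t = table.copy()
    coord_cols = ["xcorr_coord", "mi_binned", "mi_phase", "mi_permutation"]
    reg_cols = ["reg_neg_peak", "reg_pos_peak"]
    t["coordination"] = combine_standardized({c: t[c] for c in coord_cols})
    t["regularity"] = combine_standardized({c: t[c] for c in reg_cols})

    chains: dict[str, CorrectionChain] = {}
    chains["regularity"] = screen_and_correct(t, "regularity",
                                              ["modulation_depth"], alpha)
    t["regularity_corr"] = chains["regularity"].corrected
    chains["coordination"] = screen_and_correct(
        t, "coordination", ["modulation_depth", "regularity_corr"], alpha)
    t["coordination_corr"] = chains["coordination"].corrected
    chains["ckc_f1"] = screen_and_correct(
        t, "ckc_f1", ["modulation_depth", "regularity_corr", "snr_f1"], alpha)
    t["ckc_f1_corr"] = chains["ckc_f1"].corrected
    chains["ckc_f0"] = screen_and_correct(
        t, "ckc_f0", ["modulation_depth", "regularity_corr", "snr_f0"], alpha)
    t["ckc_f0_corr"] = chains["ckc_f0"].corrected

    variables = ["score1", "score2", "ckc_f0", "ckc_f1", "ckc_f0_corr",
                 "ckc_f1_corr", "coordination_corr", "regularity_corr",
                 "modulation_depth"]
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            rho, p = spearman(t[a], t[b])
            rows.append({"var1": a, "var2": b, "rho": rho, "p": p,
                         "significant": p < alpha})
    correlations = pd.DataFrame(rows)

    contrast = _zscore(t["ckc_f1"].to_numpy(float)) - _zscore(t["score1"].to_numpy(float))
    c_rho, c_p = spearman(contrast, t["score2"])

    pid = None
    if len(t) >= 10:
        pid = pid_permutation_test(t, "score1", "score2", "ckc_f1",
                                   n_permutations=n_permutations, seed=seed)
    w_stat, w_p = sps.wilcoxon(t["ckc_f0"], t["ckc_f1"])

    return {
        "table": t,
        "correlations": correlations,
        "correction_chains": chains,
        "contrast": {"values": contrast, "rho": c_rho, "p": c_p},
        "pid": pid,
        "wilcoxon_f0_vs_f1": {"statistic": float(w_stat), "p": float(w_p)},
    }
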