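"""Variance/covariance decomposition of the recursive model.

Converts structural-model parameters to their reduced (total) form and
splits every genetic variance and covariance into a direct part and a
microbiota-mediated (indirect) part:

    total variance of trait t:   s2_u,t + 2*lam_t*s_u,M,t + lam_t^2*s2_u,M
    total cov(t, M):             s_u,t,M + lam_t*s2_u,M
    total cov(AL, R):            s_u,AL,R + lam_AL*s_u,M,R + lam_R*s_u,M,AL
                                 + lam_AL*lam_R*s2_u,M

These scalar identities are exactly the entries of the matrix transform
(I3 - Lambda)^-1 Theta0 (I3 - Lambda)^-T, which both routes exploit as a
cross-check. Heritabilities, SD-standardized structural effects, highest
posterior density (HPD) intervals and the significance/relevance calls
are computed here as well, draw by draw over posterior samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "transform_covariance",
    "starred_from_scalar",
    "total_genetic_variance",
    "total_genetic_covariances",
    "heritability",
    "standardize_effect",
    "hpd_interval",
    "is_significant",
    "classify_relevant",
    "decompose_samples",
    "DecompositionResult",
]

_TRAIT_INDEX = {"AL": 0, "R": 1}


def _lam_pair(lam) -> tuple[float, float]:
    if hasattr(lam, "lambda_al"):
        return float(lam.lambda_al), float(lam.lambda_r)
    a, r = lam
    return float(a), float(r)


def _lam_matrix(lam) -> np.ndarray:
    a, r = _lam_pair(lam)
    out = np.zeros((3, 3))
    out[0, 2] = a
    out[1, 2] = r
    return out


def transform_covariance(theta0: np.ndarray, lam) -> np.ndarray:
    """Map a structural 3x3 covariance to its reduced (starred) form:
    (I3 - Lambda)^-1 theta0 (I3 - Lambda)^-T.

    The trait ordering is (AL, R, M); element (3, 3) is invariant for
    any admissible Lambda, since M has no upstream traits.
    """
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.shape != (3, 3) or not np.allclose(theta0, theta0.T, atol=1e-8):
        raise ValueError("theta0 must be a symmetric 3x3 matrix")
    inv = np.linalg.inv(np.eye(3) - _lam_matrix(lam))
    out = inv @ theta0 @ inv.T
    return (out + out.T) / 2.0


def starred_from_scalar(theta0: np.ndarray, lam) -> np.ndarray:
    """Starred matrix assembled entry by entry from the scalar partition
    identities; the independent route against :func:`transform_covariance`."""
    theta0 = np.asarray(theta0, dtype=float)
    a, r = _lam_pair(lam)
    s_al, s_r, s_m = theta0[0, 0], theta0[1, 1], theta0[2, 2]
    c_alr, c_alm, c_rm = theta0[0, 1], theta0[0, 2], theta0[1, 2]
    out = np.empty((3, 3))
    out[0, 0] = s_al + 2.0 * a * c_alm + a * a * s_m
    out[1, 1] = s_r + 2.0 * r * c_rm + r * r * s_m
    out[2, 2] = s_m
    out[0, 1] = out[1, 0] = c_alr + a * c_rm + r * c_alm + a * r * s_m
    out[0, 2] = out[2, 0] = c_alm + a * s_m
    out[1, 2] = out[2, 1] = c_rm + r * s_m
    return out


def total_genetic_variance(g0: np.ndarray, lam, trait: str) -> tuple[float, float, float]:
    """(total, direct, indirect) genetic variance for one ADG trait.

    direct = the structural genetic variance; indirect = the
    microbiota-mediated term 2*lam*cov(u_t, u_M) + lam^2*var(u_M);
    total = direct + indirect, an exact identity.
    """
    g0 = np.asarray(g0, dtype=float)
    t = _TRAIT_INDEX[trait]
    lam_t = _lam_pair(lam)[t]
    direct = float(g0[t, t])
    indirect = float(2.0 * lam_t * g0[t, 2] + lam_t**2 * g0[2, 2])
    return direct + indirect, direct, indirect


def total_genetic_covariances(g0: np.ndarray, lam) -> dict[str, float]:
    """Total/direct/indirect genetic covariances among the three traits.

    The mediated part of cov(AL, R) collects every path through M; the
    indirect part of cov(t, M) is lam_t * var(u_M).
    """
    g0 = np.asarray(g0, dtype=float)
    a, r = _lam_pair(lam)
    direct_alr = float(g0[0, 1])
    mediated_alr = float(a * g0[2, 1] + r * g0[2, 0] + a * r * g0[2, 2])
    out = {
        "cov_AL_R_direct": direct_alr,
        "cov_AL_R_mediated": mediated_alr,
        "cov_AL_R_total": direct_alr + mediated_alr,
    }
    for trait, lam_t in (("AL", a), ("R", r)):
        t = _TRAIT_INDEX[trait]
        direct = float(g0[t, 2])
        indirect = float(lam_t * g0[2, 2])
        out[f"cov_{trait}_M_direct"] = direct
        out[f"cov_{trait}_M_indirect"] = indirect
        out[f"cov_{trait}_M_total"] = direct + indirect
    return out


def heritability(
    l0: np.ndarray,
    c0: np.ndarray,
    g0: np.ndarray,
    r0: np.ndarray,
    lam,
    trait: str,
    mode: str = "direct",
) -> float:
    """Genetic variance over total phenotypic variance for one trait.

    ``mode="direct"`` uses the structural (unstarred) components;
    ``mode="total"`` uses the reduced-model (starred) components in both
    numerator and denominator. ``trait`` may be "AL", "R" or "M".
    """
    mats = [np.asarray(m, dtype=float) for m in (l0, c0, g0)]
    r0 = np.asarray(r0, dtype=float)
    if r0.ndim == 1:
        r0 = np.diag(r0)
    mats.append(r0)
    t = {"AL": 0, "R": 1, "M": 2}[trait]
    if mode == "total":
        mats = [transform_covariance(m, lam) for m in mats]
    elif mode != "direct":
        raise ValueError(f"mode must be 'direct' or 'total', got {mode!r}")
    l0_, c0_, g0_, r0_ = mats
    denom = l0_[t, t] + c0_[t, t] + g0_[t, t] + r0_[t, t]
    if denom <= 0:
        raise ValueError("zero phenotypic variance in heritability denominator")
    return float(g0_[t, t] / denom)


def standardize_effect(lambda_mean: float, trait_sd: float) -> float:
    """Structural coefficient in phenotypic SD units: lambda / SD."""
    if trait_sd <= 0:
        raise ValueError("trait SD must be positive")
    return float(lambda_mean) / float(trait_sd)


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(prob * n) sorted draws.

    Ties between equally short windows are broken toward the lowest
    starting index, making the result deterministic.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPD interval")
    if not 0 < prob < 1:
        raise ValueError("prob must lie strictly between 0 and 1")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    start = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[start]), float(x[start + m - 1])


def is_significant(draws, prob: float = 0.95) -> bool:
    """True when the HPD interval at ``prob`` excludes zero."""
    low, high = hpd_interval(draws, prob)
    return bool(low > 0.0 or high < 0.0)


def classify_relevant(std_effect: float, threshold: float = 0.2) -> bool:
    """True when |standardized effect| is equal to or higher than the
    relevance threshold (0.2 SD by default)."""
    return bool(abs(std_effect) >= threshold)


@dataclass
class DecompositionResult:
    """Posterior summary of one OTU analysis.

    All decomposed quantities are computed per draw and then averaged
    over the posterior (the partition identities are nonlinear in the
    structural coefficients, so plugging in posterior means would bias
    them). ``trait_sd`` records which SD standardized the effects.
    """

    otu_id: str | None
    summary: dict[str, float]
    flags: dict[str, bool]
    trait_sd: dict[str, float]

    def to_row(self, taxonomy: str = "") -> dict:
        row: dict = {"otu_id": self.otu_id, "taxonomy": taxonomy}
        row.update(self.summary)
        row.update({k: bool(v) for k, v in self.flags.items()})
        return row


def decompose_samples(
    samples,
    trait_sd: dict[str, float],
    hpd_prob: float = 0.95,
    relevance_threshold: float = 0.2,
) -> DecompositionResult:
    """Apply the full decomposition draw-by-draw to posterior samples.

    ``trait_sd`` maps "AL" and "R" to the phenotypic SDs used to express
    structural coefficients in SD units (observed SDs by default in the
    calling pipeline, configurable to model-based SDs).
    """
    n = samples.n_draws
    lam_draws = {"AL": samples.lambda_al, "R": samples.lambda_r}
    summary: dict[str, float] = {}
    flags: dict[str, bool] = {}

    acc: dict[str, np.ndarray] = {}

    def _push(key: str, i: int, value: float) -> None:
        if key not in acc:
            acc[key] = np.empty(n)
        acc[key][i] = value

    for i in range(n):
        lam = samples.structural(i)
        cs = samples.covariance_set(i)
        for trait in ("AL", "R"):
            total, direct, indirect = total_genetic_variance(cs.G0, lam, trait)
            _push(f"gvar_{trait}_total", i, total)
            _push(f"gvar_{trait}_direct", i, direct)
            _push(f"gvar_{trait}_indirect", i, indirect)
            for mode in ("direct", "total"):
                _push(
                    f"h2_{trait}_{mode}",
                    i,
                    heritability(cs.L0, cs.C0, cs.G0, cs.R0_diag, lam, trait, mode),
                )
        for mode in ("direct", "total"):
            _push(f"h2_M_{mode}", i, heritability(cs.L0, cs.C0, cs.G0, cs.R0_diag, lam, "M", mode))
        for key, value in total_genetic_covariances(cs.G0, lam).items():
            _push(key, i, value)

    for key, arr in acc.items():
        summary[f"{key}"] = float(arr.mean())

    for trait in ("AL", "R"):
        draws = lam_draws[trait]
        low, high = hpd_interval(draws, hpd_prob)
        mean = float(draws.mean())
        std_effect = standardize_effect(mean, trait_sd[trait])
        summary[f"lambda_{trait}_mean"] = mean
        summary[f"lambda_{trait}_median"] = float(np.median(draws))
        summary[f"lambda_{trait}_hpd_low"] = low
        summary[f"lambda_{trait}_hpd_high"] = high
        summary[f"std_effect_{trait}"] = std_effect
        flags[f"significant_{trait}"] = is_significant(draws, hpd_prob)
        flags[f"relevant_{trait}"] = classify_relevant(std_effect, relevance_threshold)

    return DecompositionResult(
        otu_id=getattr(samples, "otu_id", None),
        summary=summary,
        flags=flags,
        trait_sd=dict(trait_sd),
    )
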