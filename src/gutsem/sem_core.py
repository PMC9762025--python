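"""Bayesian Gibbs sampler for the three-trait recursive structural model.

The traits are, in fixed order, average daily gain under ad libitum
feeding (ADG_AL), average daily gain under restricted feeding (ADG_R)
and the normalized abundance of one microbial feature (M). The model is

    y = (Lambda (x) I_n) y + X b + Z_l l + Z_c c + Z_u u + e,

where Lambda has exactly two free entries: the structural coefficients
lambda_AL<-M and lambda_R<-M in positions (AL, M) and (R, M). Litter (l)
and cage (c) effects have 3x3 covariance matrices L0 and C0; genomic
effects u have covariance G0 (x) G with G the genomic relationship
matrix; residuals are independent across traits (diagonal R0), which
makes the acyclic structure identifiable and the likelihood Jacobian
unity. Exactly one of the two ADG traits is observed per animal
(missing by design); M is observed for all animals.

Sampler structure, one scan per iteration:

1. data augmentation of the missing ADG records from their trait
   residual conditionals;
2. fixed effects b (flat prior), then litter, cage and genomic random
   effects from their multivariate-normal full conditionals; the
   genomic block is sampled in the eigenbasis of G, where the 3n-variate
   conditional factors into n independent trivariate problems;
3. the structural coefficients from scalar normal conditionals (flat
   prior by default, optionally normal);
4. L0, C0, G0 from inverse-Wishart conditionals (G0 weighted by G^-1),
   and the R0 diagonal from scaled-inverse-chi-square conditionals.

A fixed seed gives a bit-reproducible chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "TRAITS",
    "StructuralCoefficients",
    "CovarianceSet",
    "SemDataset",
    "ChainConfig",
    "PosteriorSamples",
    "GibbsSampler",
    "gibbs_sem",
    "reduced_model_predictive_check",
    "effective_sample_size",
    "save_chain",
    "load_chain",
]

TRAITS = ("AL", "R", "M")


@dataclass
class StructuralCoefficients:
    """The two free entries of Lambda: effects of M on ADG_AL and ADG_R
    (g/day per CSS-normalized unit)."""

    lambda_al: float
    lambda_r: float

    def matrix(self) -> np.ndarray:
        lam = np.zeros((3, 3))
        lam[0, 2] = self.lambda_al
        lam[1, 2] = self.lambda_r
        return lam


@dataclass
class CovarianceSet:
    """The model's 3x3 (co)variance matrices, trait order (AL, R, M).

    L0 (litter), C0 (cage) and G0 (genomic) are symmetric positive
    definite; R0 is diagonal with positive entries (stored as the
    diagonal), the identifiability condition for the acyclic structure.
    """

    L0: np.ndarray
    C0: np.ndarray
    G0: np.ndarray
    R0_diag: np.ndarray

    def __post_init__(self) -> None:
        for name in ("L0", "C0", "G0"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            np.linalg.cholesky(m)  # positive definiteness
            setattr(self, name, m)
        r = np.asarray(self.R0_diag, dtype=float).ravel()
        if r.shape != (3,) or np.any(r <= 0):
            raise ValueError("R0 diagonal must be three positive variances")
        self.R0_diag = r

    @property
    def R0(self) -> np.ndarray:
        return np.diag(self.R0_diag)


@dataclass
class SemDataset:
    """Per-animal records aligned with the GRM ordering.

    Exactly one of ``y_al``/``y_r`` is observed per animal (NaN marks the
    structurally missing trait); ``y_m`` is observed for all animals.
    """

    animal_ids: list[str]
    y_al: np.ndarray
    y_r: np.ndarray
    y_m: np.ndarray
    batch_farm: np.ndarray
    ww_class: np.ndarray
    litter: np.ndarray
    cage: np.ndarray
    grm: object  # GenomicRelationshipMatrix (values: n x n symmetric PD)
    otu_id: str | None = None

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        for name in ("y_al", "y_r", "y_m", "batch_farm", "ww_class", "litter", "cage"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.y_al = self.y_al.astype(float)
        self.y_r = self.y_r.astype(float)
        self.y_m = self.y_m.astype(float)
        one_each = np.isnan(self.y_al) ^ np.isnan(self.y_r)
        if not one_each.all():
            raise ValueError("exactly one of ADG_AL/ADG_R must be observed per animal")
        if np.isnan(self.y_m).any():
            raise ValueError("the microbial trait must be observed for all animals")
        for name in ("batch_farm", "ww_class", "litter", "cage"):
            codes = getattr(self, name).astype(int)
            if codes.min() < 0:
                raise ValueError(f"{name} codes must be non-negative integers")
            setattr(self, name, codes)
        grm_shape = getattr(self.grm, "shape", None)
        if grm_shape is None:
            grm_shape = np.asarray(self.grm.values).shape
        if tuple(grm_shape) != (n, n):
            raise ValueError("GRM dimension must equal the number of animals")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_litters(self) -> int:
        return int(self.litter.max()) + 1

    @property
    def n_cages(self) -> int:
        return int(self.cage.max()) + 1

    def design_matrix(self) -> np.ndarray:
        """Intercept + batch-farm dummies (first level dropped) + weaning
        weight class dummy."""
        n = self.n_animals
        cols = [np.ones(n)]
        for lvl in range(1, int(self.batch_farm.max()) + 1):
            cols.append((self.batch_farm == lvl).astype(float))
        if self.ww_class.max() > 0:
            cols.append((self.ww_class == 1).astype(float))
        return np.column_stack(cols)


@dataclass
class ChainConfig:
    """MCMC settings and priors.

    The desk-scale default (20,000 iterations, 5,000 burn-in, thin 10)
    keeps a single fit interactive; full-scale runs (e.g. 1,000,000 /
    300,000 / 100) are a matter of changing these numbers. Priors:
    inverse-Wishart(df ``iw_df``, scale = 0.5 x empirical phenotype
    variances on the diagonal) for L0, C0, G0; scaled-inverse-chi-square
    (df ``residual_df``, scale 0.5 x empirical variance) per residual;
    flat for b; flat for the structural coefficients unless
    ``lambda_prior_var`` gives a proper normal prior variance.
    """

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    iw_df: float = 5.0
    residual_df: float = 4.0
    prior_scale_factor: float = 0.5
    lambda_prior_var: float | None = None
    include_random_effects: bool = True
    sample_fixed_effects: bool = True
    overflow_guard: float = 1e10

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned posterior draws from one OTU analysis."""

    lambda_al: np.ndarray
    lambda_r: np.ndarray
    L0: np.ndarray  # (n_draws, 3, 3)
    C0: np.ndarray
    G0: np.ndarray
    R0: np.ndarray  # (n_draws, 3) diagonals
    config: ChainConfig
    otu_id: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.lambda_al)

    def covariance_set(self, i: int) -> CovarianceSet:
        return CovarianceSet(self.L0[i], self.C0[i], self.G0[i], self.R0[i])

    def structural(self, i: int) -> StructuralCoefficients:
        return StructuralCoefficients(float(self.lambda_al[i]), float(self.lambda_r[i]))

    def to_frame(self) -> pd.DataFrame:
        """Columnar layout, one row per saved draw."""
        cols: dict[str, np.ndarray] = {
            "lambda_AL": self.lambda_al,
            "lambda_R": self.lambda_r,
        }
        for name, arr in (("L0", self.L0), ("C0", self.C0), ("G0", self.G0)):
            for i in range(3):
                for j in range(i, 3):
                    cols[f"{name}_{i + 1}{j + 1}"] = arr[:, i, j]
        for i in range(3):
            cols[f"R0_{i + 1}{i + 1}"] = self.R0[:, i]
        return pd.DataFrame(cols)


def _inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) via the Bartlett decomposition."""
    p = scale.shape[0]
    lp = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((p, p))
    rows, cols = np.tril_indices(p, -1)
    a[rows, cols] = rng.standard_normal(rows.size)
    a[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    la = lp @ a
    w = la @ la.T
    out = np.linalg.inv(w)
    return (out + out.T) / 2.0


def _batched_mvn3(rng, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Draw from q independent trivariate normals with precision ``prec``
    (q,3,3) and precision-weighted mean ``rhs`` (q,3)."""
    cov = np.linalg.inv(prec)
    mean = np.einsum("qij,qj->qi", cov, rhs)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(rhs.shape)
    return mean + np.einsum("qij,qj->qi", chol, z)


class GibbsSampler:
    """Stateful Gibbs sampler exposing one full conditional scan at a time.

    :func:`gibbs_sem` is the ordinary entry point; the class exists so
    calibration checks (e.g. joint-distribution tests that alternate
    posterior scans with data simulation) can drive the chain scan by
    scan and replace the phenotypes between scans.
    """

    def __init__(self, data: SemDataset, config: ChainConfig):
        self.data = data
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.n = n = data.n_animals
        self.x = x = data.design_matrix()
        self.p = x.shape[1]

        self.litter, self.cage = data.litter, data.cage
        self.q_l, self.q_c = data.n_litters, data.n_cages
        self.counts_l = np.bincount(self.litter, minlength=self.q_l).astype(float)
        self.counts_c = np.bincount(self.cage, minlength=self.q_c).astype(float)

        xtx = x.T @ x
        self.lx = np.linalg.cholesky(xtx)
        self.xtx_factor = cho_factor(xtx, lower=True)

        g = np.asarray(data.grm.values, dtype=float)
        self.d_eig, self.u_eig = np.linalg.eigh(g)
        if self.d_eig.min() <= 0:
            raise ValueError(
                f"GRM is not positive definite (min eigenvalue {self.d_eig.min():.3g}); "
                "blend the GRM with the identity before fitting"
            )

        self.miss_al = np.isnan(data.y_al)
        self.miss_r = np.isnan(data.y_r)
        self.y_m = data.y_m
        self.smm = float(self.y_m @ self.y_m)

        emp_var = np.array(
            [
                np.nanvar(data.y_al, ddof=1),
                np.nanvar(data.y_r, ddof=1),
                np.var(self.y_m, ddof=1),
            ]
        )
        if np.any(emp_var <= 0):
            raise ValueError("each trait needs positive empirical variance")
        self.emp_var = emp_var

        self.nu0 = config.iw_df
        self.s0 = np.diag(config.prior_scale_factor * emp_var)
        self.nu_e = config.residual_df
        self.s0e = config.prior_scale_factor * emp_var
        self.guard = config.overflow_guard * emp_var.max()
        self.lam_prec0 = (
            0.0 if config.lambda_prior_var is None else 1.0 / config.lambda_prior_var
        )
        self.sample_res = config.include_random_effects

        # state
        y = np.column_stack([data.y_al, data.y_r, self.y_m])
        obs_mean = np.array([np.nanmean(y[:, t]) for t in range(3)])
        for t in range(2):
            y[np.isnan(y[:, t]), t] = obs_mean[t]
        self.y = y
        self.lam = np.zeros(2)
        self.b = np.zeros((self.p, 3))
        self.b[0] = obs_mean
        self.eff_l = np.zeros((self.q_l, 3))
        self.eff_c = np.zeros((self.q_c, 3))
        self.eff_u = np.zeros((n, 3))
        self.u_rot = np.zeros((n, 3))
        self.L0 = np.diag(emp_var * 0.25)
        self.C0 = np.diag(emp_var * 0.25)
        self.G0 = np.diag(emp_var * 0.25)
        self.r0 = emp_var * 0.5
        self.iteration = 0

    # -- state helpers ----------------------------------------------------

    def _ranef(self):
        if not self.sample_res:
            return 0.0
        return self.eff_l[self.litter] + self.eff_c[self.cage] + self.eff_u

    def simulate_phenotypes(self) -> None:
        """Replace the phenotypes with a draw from the likelihood at the
        current parameter values (used by joint-distribution checks).

        The recursive build mirrors the generative model: the microbial
        trait first, then each growth trait with its structural term.
        """
        mean = self.x @ self.b + self._ranef()
        e = self.rng.standard_normal((self.n, 3)) * np.sqrt(self.r0)
        y = np.empty_like(self.y)
        y[:, 2] = mean[:, 2] + e[:, 2]
        y[:, 0] = mean[:, 0] + self.lam[0] * y[:, 2] + e[:, 0]
        y[:, 1] = mean[:, 1] + self.lam[1] * y[:, 2] + e[:, 1]
        self.y = y
        self.y_m = y[:, 2]
        self.smm = float(self.y_m @ self.y_m)

    # -- one full Gibbs scan ----------------------------------------------

    def scan(self) -> None:
        rng = self.rng
        y, y_m, r0, lam = self.y, self.y_m, self.r0, self.lam
        litter, cage = self.litter, self.cage
        eye3 = np.arange(3)

        loc = self.x @ self.b
        if self.sample_res:
            loc = loc + self._ranef()

        # -- 1. augment structurally missing ADG records
        miss_al, miss_r = self.miss_al, self.miss_r
        y[miss_al, 0] = (
            lam[0] * y_m[miss_al]
            + loc[miss_al, 0]
            + rng.standard_normal(miss_al.sum()) * np.sqrt(r0[0])
        )
        y[miss_r, 1] = (
            lam[1] * y_m[miss_r]
            + loc[miss_r, 1]
            + rng.standard_normal(miss_r.sum()) * np.sqrt(r0[1])
        )

        # transformed (structural) responses
        yt = np.column_stack([y[:, 0] - lam[0] * y_m, y[:, 1] - lam[1] * y_m, y_m])

        # -- 2a. fixed effects (flat prior); optionally held at known values
        if self.config.sample_fixed_effects:
            resid = yt - (self._ranef() if self.sample_res else 0.0)
            bhat = cho_solve(self.xtx_factor, self.x.T @ resid)
            z = rng.standard_normal((self.p, 3))
            self.b = bhat + solve_triangular(self.lx.T, z, lower=False) * np.sqrt(r0)
        xb = self.x @ self.b

        if self.sample_res:
            # -- 2b. litter effects: independent 3x3 conditionals per litter
            l0_inv = np.linalg.inv(self.L0)
            res = yt - xb - self.eff_c[cage] - self.eff_u
            rhs = np.column_stack(
                [np.bincount(litter, weights=res[:, t], minlength=self.q_l) for t in range(3)]
            ) / r0
            prec = np.broadcast_to(l0_inv, (self.q_l, 3, 3)).copy()
            prec[:, eye3, eye3] += self.counts_l[:, None] / r0
            self.eff_l = _batched_mvn3(rng, prec, rhs)

            # -- 2c. cage effects
            c0_inv = np.linalg.inv(self.C0)
            res = yt - xb - self.eff_l[litter] - self.eff_u
            rhs = np.column_stack(
                [np.bincount(cage, weights=res[:, t], minlength=self.q_c) for t in range(3)]
            ) / r0
            prec = np.broadcast_to(c0_inv, (self.q_c, 3, 3)).copy()
            prec[:, eye3, eye3] += self.counts_c[:, None] / r0
            self.eff_c = _batched_mvn3(rng, prec, rhs)

            # -- 2d. genomic effects in the eigenbasis of G
            g0_inv = np.linalg.inv(self.G0)
            res = yt - xb - self.eff_l[litter] - self.eff_c[cage]
            rhs_rot = (self.u_eig.T @ res) / r0
            prec = (g0_inv[None, :, :] / self.d_eig[:, None, None]).copy()
            prec[:, eye3, eye3] += 1.0 / r0
            self.u_rot = _batched_mvn3(rng, prec, rhs_rot)
            self.eff_u = self.u_eig @ self.u_rot

        # -- 3. structural coefficients, scalar normal conditionals
        base = xb + (self._ranef() if self.sample_res else 0.0)
        for t in range(2):
            r_t = y[:, t] - base[:, t]
            prec_lam = self.smm / r0[t] + self.lam_prec0
            mean_lam = (y_m @ r_t) / r0[t] / prec_lam
            lam[t] = mean_lam + rng.standard_normal() / np.sqrt(prec_lam)

        if self.sample_res:
            # -- 4. covariance matrices, inverse-Wishart conditionals
            self.L0 = _inv_wishart(rng, self.nu0 + self.q_l, self.s0 + self.eff_l.T @ self.eff_l)
            self.C0 = _inv_wishart(rng, self.nu0 + self.q_c, self.s0 + self.eff_c.T @ self.eff_c)
            scatter_u = self.u_rot.T @ (self.u_rot / self.d_eig[:, None])
            self.G0 = _inv_wishart(rng, self.nu0 + self.n, self.s0 + scatter_u)

        # -- 5. residual variances, scaled-inverse-chi-square conditionals
        e = np.column_stack(
            [y[:, 0] - lam[0] * y_m, y[:, 1] - lam[1] * y_m, y_m]
        ) - base
        sse = np.einsum("ij,ij->j", e, e)
        self.r0 = (self.nu_e * self.s0e + sse) / rng.chisquare(self.nu_e + self.n, size=3)

        self.iteration += 1
        if np.any(self.r0 > self.guard) or np.any(np.diagonal(self.G0) > self.guard):
            raise RuntimeError(
                f"divergent chain at iteration {self.iteration}: a variance exceeded "
                "the overflow guard; consider stronger priors"
            )


def gibbs_sem(data: SemDataset, config: ChainConfig) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned posterior draws.

    With ``config.include_random_effects=False`` the litter, cage and
    genomic effects are pinned at zero and their covariances are not
    sampled: the model degenerates to a fixed-effects regression with
    M as a covariate, which is useful as a closed-form cross-check.
    """
    sampler = GibbsSampler(data, config)
    n_saved = config.n_saved
    out_lam = np.empty((n_saved, 2))
    out_l0 = np.empty((n_saved, 3, 3))
    out_c0 = np.empty((n_saved, 3, 3))
    out_g0 = np.empty((n_saved, 3, 3))
    out_r0 = np.empty((n_saved, 3))
    saved = 0

    for it in range(1, config.n_iter + 1):
        sampler.scan()
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            # positive definiteness of every saved draw, asserted at save time
            np.linalg.cholesky(sampler.L0)
            np.linalg.cholesky(sampler.C0)
            np.linalg.cholesky(sampler.G0)
            assert np.all(sampler.r0 > 0)
            out_lam[saved] = sampler.lam
            out_l0[saved] = sampler.L0
            out_c0[saved] = sampler.C0
            out_g0[saved] = sampler.G0
            out_r0[saved] = sampler.r0
            saved += 1

    return PosteriorSamples(
        lambda_al=out_lam[:saved, 0].copy(),
        lambda_r=out_lam[:saved, 1].copy(),
        L0=out_l0[:saved],
        C0=out_c0[:saved],
        G0=out_g0[:saved],
        R0=out_r0[:saved],
        config=config,
        otu_id=data.otu_id,
        metadata={
            "n_animals": sampler.n,
            "n_litters": sampler.q_l,
            "n_cages": sampler.q_c,
        },
    )


def reduced_model_predictive_check(
    samples: PosteriorSamples, n_check: int = 50
) -> dict:
    """Verify that the SEM and its reduced multiple-trait form imply the
    same phenotype covariances, draw by draw.

    For a subsample of posterior draws the total phenotypic covariance is
    computed twice: once as (I - Lambda)^-1 (L0+C0+G0+R0) (I - Lambda)^-T
    and once by summing the four starred matrices obtained from the
    scalar variance-partition identities. The two routes must agree to
    numerical precision.
    """
    from . import decomposition as dec

    idx = np.linspace(0, samples.n_draws - 1, min(n_check, samples.n_draws)).astype(int)
    max_diff = 0.0
    eye = np.eye(3)
    for i in idx:
        lam = samples.structural(int(i))
        cs = samples.covariance_set(int(i))
        total = cs.L0 + cs.C0 + cs.G0 + cs.R0
        inv = np.linalg.inv(eye - lam.matrix())
        sigma_sem = inv @ total @ inv.T
        sigma_mtam = sum(
            dec.starred_from_scalar(theta, lam)
            for theta in (cs.L0, cs.C0, cs.G0, cs.R0)
        )
        max_diff = max(max_diff, float(np.abs(sigma_sem - sigma_mtam).max()))
    return {"n_checked": len(idx), "max_abs_discrepancy": max_diff}


def effective_sample_size(draws) -> float:
    """Autocorrelation-based effective sample size of a scalar chain.

    Uses the FFT autocovariance with Geyer's initial-positive-sequence
    truncation. A constant chain is degenerate: a warning is issued and
    the nominal sample size is returned.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws for an ESS estimate")
    if np.ptp(x) == 0:
        warnings.warn("constant chain: ESS is degenerate, reporting n", stacklevel=2)
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs, keep while positive
    n_pairs = n // 2
    gamma = rho[0 : 2 * n_pairs : 2] + rho[1 : 2 * n_pairs : 2]
    tau = -1.0
    for g_k in gamma:
        if g_k <= 0:
            break
        tau += 2.0 * g_k
    tau = max(tau, 1.0 / n)
    return float(np.clip(n / tau, 1.0, n))


def save_chain(samples: PosteriorSamples, path) -> None:
    """Write draws as columnar TSV with a JSON sidecar of config/metadata."""
    path = Path(path)
    samples.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "otu_id": samples.otu_id,
        "config": {
            k: v for k, v in vars(samples.config).items() if not k.startswith("_")
        },
        "metadata": samples.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_chain(path) -> PosteriorSamples:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = len(df)

    def mat(name):
        out = np.empty((n, 3, 3))
        for i in range(3):
            for j in range(i, 3):
                out[:, i, j] = out[:, j, i] = df[f"{name}_{i + 1}{j + 1}"]
        return out

    cfg = ChainConfig(**sidecar["config"])
    return PosteriorSamples(
        lambda_al=df["lambda_AL"].to_numpy(),
        lambda_r=df["lambda_R"].to_numpy(),
        L0=mat("L0"),
        C0=mat("C0"),
        G0=mat("G0"),
        R0=np.column_stack([df[f"R0_{i + 1}{i + 1}"] for i in range(3)]),
        config=cfg,
        otu_id=sidecar.get("otu_id"),
        metadata=sidecar.get("metadata", {}),
    )
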