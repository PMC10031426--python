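"""Bayesian bivariate animal model for sex-specific variance components.

Body mass is modelled as a bivariate Gaussian trait -- the female and the
male expression of size -- where every individual is observed for exactly
the trait of its own sex.  Random effects and their covariance kernels:

* autosomal additive: per-individual breeding values for both trait
  expressions, covariance ``G (x) A`` with ``G`` the free 2x2 cross-sex
  covariance matrix (this is where ``r_mf`` lives);
* dominance and X-linked additive: one effect vector per sex with the
  corresponding pedigree kernel; the cross-sex covariances of these
  components are structurally fixed to zero, so the sexes' vectors are
  independent;
* Y-linked: an i.i.d. patriline-level effect on the male trait only
  (exactly equivalent to the 0/1 patriline kernel);
* maternal environment: an i.i.d. dam-level effect per offspring sex;
* residual: sex-specific, with the cross-trait residual covariance fixed to
  zero (no individual expresses both traits, so it is unidentifiable).

Estimation is by Gibbs sampling.  Latent effects are kept only for observed
individuals (the rest are marginalized through the restricted kernels).  Two
non-standard moves keep the chain mobile where naive conditional updates
stall: every scalar variance is updated from its *marginal* likelihood with
its own effect vector integrated out (cheap in the kernel eigenbasis), and
the 2x2 autosomal covariance gets an interweaving move that re-fits its
Cholesky factor with the whitened breeding values held fixed, on top of the
conjugate inverse-Wishart update.

A direct maximum-likelihood fit of the same covariance structure
(:func:`ml_fit`) provides an independent verification route and the
likelihood-ratio test for single components on the boundary
(:func:`lrt_component`), using the 50:50 chi-square mixture reference
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .components import PARAM_NAMES
from .pedigree import FEMALE, Pedigree
from .relatedness import additive_matrix, dominance_matrix, x_kinship, y_patrilines

# "D" / "X" expand to both sexes; the per-sex forms ("Df", "Xm", ...) allow
# dropping a single boundary component, e.g. for likelihood-ratio tests
ALL_COMPONENTS = ("Aa", "D", "Df", "Dm", "X", "Xf", "Xm", "Y", "ME")

_EIG_FLOOR = 1e-8


class ModelError(ValueError):
    pass


class DegenerateDataError(ValueError):
    """Raised when the response carries no usable variation."""


@dataclass
class MCMCSettings:
    iterations: int = 5000
    burn_in: int = 1000
    thin: int = 4
    chains: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ModelError("iterations must exceed burn_in")


@dataclass
class ModelSpec:
    """Which components to fit, with priors and chain settings.

    Priors: the 2x2 autosomal block uses an inverse-Wishart with ``g_nu``
    degrees of belief and scale ``g_scale * V_P * I`` (V_P = observed
    phenotypic variance); every scalar variance uses a weak
    scaled-inverse-chi-square with ``nu`` degrees of belief and scale
    ``s2 * V_P``.  Defaults are deliberately weak.
    """

    components: tuple[str, ...] = ("Aa", "D", "X", "Y", "ME")
    block_effect: bool = False  # categorical 'block' column as fixed effect
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    # G prior: nu = p + 1 makes the marginal cross-sex correlation uniform;
    # the scale is a fraction of the observed phenotypic variance.  A much
    # smaller scale concentrates prior mass on near-singular G and traps the
    # correlation at +-1.
    g_nu: float = 3.0
    g_scale: float = 0.05
    # scalar prior: close to scale-invariant; nu much larger would place the
    # prior mode at a substantially nonzero fraction of V_P and bias weakly
    # identified components away from zero
    nu: float = 0.02
    s2: float = 1.0

    def __post_init__(self):
        bad = set(self.components) - set(ALL_COMPONENTS)
        if bad:
            raise ModelError(f"unknown components: {sorted(bad)}")


@dataclass
class _EigKernel:
    """Eigendecomposition of a kernel restricted to one sex's observed rows."""

    rows: np.ndarray      # positions within the observed vector
    U: np.ndarray
    lam: np.ndarray

    @classmethod
    def from_matrix(cls, K: np.ndarray, rows: np.ndarray) -> "_EigKernel":
        lam, U = np.linalg.eigh(K)
        return cls(rows, U, np.clip(lam, _EIG_FLOOR, None))


@dataclass
class _Grouped:
    """Grouped i.i.d. random effect (patriline or dam)."""

    rows: np.ndarray      # observed-row positions carrying the effect
    codes: np.ndarray     # group index per row
    n_groups: int


@dataclass
class Design:
    """Model matrices and kernels for one pedigree + phenotype dataset."""

    ids: list[str]
    y: np.ndarray
    female: np.ndarray
    X_fix: np.ndarray
    fix_names: list[str]
    components: tuple[str, ...]
    A_obs: np.ndarray | None = None
    A_inv: np.ndarray | None = None
    kernels: dict[str, _EigKernel] = field(default_factory=dict)   # Df, Dm, Xf, Xm
    groups: dict[str, _Grouped] = field(default_factory=dict)      # Y, MEf, MEm

    @property
    def n(self) -> int:
        return len(self.y)


def build_design(ped: Pedigree, phen: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble response, fixed effects and relatedness structures.

    Every phenotyped id must be in the pedigree and carry exactly one record,
    observed for the trait of its own sex.  Kernels are restricted to the
    observed individuals (and the relevant sex for D and X), which
    marginalizes all unobserved relatives exactly.
    """
    if phen["id"].duplicated().any():
        dup = phen.loc[phen["id"].duplicated(), "id"].iloc[0]
        raise ModelError(f"individual {dup!r} has more than one record")
    unknown = [i for i in phen["id"] if i not in ped]
    if unknown:
        raise ModelError(f"phenotype for unknown id {unknown[0]!r}")

    phen = phen.reset_index(drop=True)
    ids = phen["id"].tolist()
    ped_sex = {r.id: r.sex for r in ped.records}
    mismatch = [i for i, s in zip(ids, phen["sex"]) if ped_sex[i] != s]
    if mismatch:
        raise ModelError(f"sex of {mismatch[0]!r} disagrees with the pedigree")

    y = phen["value"].to_numpy(dtype=float)
    female = (phen["sex"] == FEMALE).to_numpy()
    for sex_mask, name in ((female, "female"), (~female, "male")):
        if sex_mask.any() and np.var(y[sex_mask]) <= 0:
            raise DegenerateDataError(f"{name} response is constant")

    # fixed effects: one intercept per trait (+ optional block contrasts)
    cols = [female.astype(float), (~female).astype(float)]
    names = ["mu_f", "mu_m"]
    if spec.block_effect and "block" in phen.columns:
        levels = sorted(phen["block"].unique())[1:]
        for lev in levels:
            ind = (phen["block"] == lev).to_numpy(dtype=float)
            cols += [ind * female, ind * ~female]
            names += [f"block[{lev}]_f", f"block[{lev}]_m"]
    X_fix = np.column_stack(cols)

    design = Design(ids, y, female, X_fix, names, tuple(spec.components))
    obs_idx = np.array([ped.index_of(i) for i in ids])
    rows_f = np.where(female)[0]
    rows_m = np.where(~female)[0]

    A = additive_matrix(ped).values
    if "Aa" in spec.components:
        A_obs = A[np.ix_(obs_idx, obs_idx)]
        design.A_obs = A_obs
        design.A_inv = np.linalg.inv(A_obs)
    comps = set(spec.components)
    want = {key: key in comps or key[0] in comps for key in ("Df", "Dm", "Xf", "Xm")}
    if want["Df"] or want["Dm"]:
        D = dominance_matrix(ped, A).values
        Dobs = D[np.ix_(obs_idx, obs_idx)]
        if want["Df"] and rows_f.size:
            design.kernels["Df"] = _EigKernel.from_matrix(
                Dobs[np.ix_(rows_f, rows_f)], rows_f)
        if want["Dm"] and rows_m.size:
            design.kernels["Dm"] = _EigKernel.from_matrix(
                Dobs[np.ix_(rows_m, rows_m)], rows_m)
    if want["Xf"] or want["Xm"]:
        phi = x_kinship(ped)[np.ix_(obs_idx, obs_idx)]
        if want["Xf"] and rows_f.size:
            design.kernels["Xf"] = _EigKernel.from_matrix(
                2.0 * phi[np.ix_(rows_f, rows_f)], rows_f)
        if want["Xm"] and rows_m.size:
            design.kernels["Xm"] = _EigKernel.from_matrix(
                phi[np.ix_(rows_m, rows_m)], rows_m)
    if "Y" in spec.components and rows_m.size:
        pat = y_patrilines(ped)
        labels = [pat[i] for i in np.array(ids, dtype=object)[rows_m]]
        uniq, codes = np.unique(labels, return_inverse=True)
        design.groups["Y"] = _Grouped(rows_m, codes, len(uniq))
    if "ME" in spec.components:
        dams = phen["dam"].to_numpy(dtype=object)
        for rows, key in ((rows_f, "MEf"), (rows_m, "MEm")):
            sub = rows[dams[rows] != "0"]
            if sub.size:
                uniq, codes = np.unique(dams[sub], return_inverse=True)
                design.groups[key] = _Grouped(sub, codes, len(uniq))
    return design


@dataclass
class PosteriorSamples:
    """Retained draws of all variance components plus chain metadata."""

    draws: pd.DataFrame      # columns: PARAM_NAMES + fixed effects + chain
    meta: dict

    def __len__(self) -> int:
        return len(self.draws)

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def ess(self, name: str) -> float:
        import arviz as az

        x = self._by_chain(name)
        return float(az.ess(az.convert_to_dataset(x)).x.values)

    def rhat(self, name: str) -> float:
        import arviz as az

        x = self._by_chain(name)
        if x.shape[0] < 2:  # split-chain diagnostic needs >= 2 chains
            half = x.shape[1] // 2
            x = np.stack([x[0, :half], x[0, half: 2 * half]])
        return float(az.rhat(az.convert_to_dataset(x)).x.values)

    def _by_chain(self, name: str) -> np.ndarray:
        g = self.draws.groupby("chain")[name]
        per = min(g.size())
        return np.stack([v.to_numpy()[:per] for _, v in g])


def _sample_mvn_prec(P: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) via Cholesky of the precision."""
    c, low = sla.cho_factor(P, lower=True, check_finite=False)
    mu = sla.cho_solve((c, low), b, check_finite=False)
    z = rng.standard_normal(len(b))
    return mu + sla.solve_triangular(c, z, lower=True, trans="T", check_finite=False)


def _inv_chi2(rng, nu: float, ss: float) -> float:
    return ss / rng.chisquare(nu) if nu > 0 else 0.0


class _ScalarComp:
    """State of one scalar-variance random effect."""

    def __init__(self, n_levels: int, s2x: float):
        self.xi = np.zeros(n_levels)
        self.s2x = s2x

    @property
    def variance(self) -> float:
        return self.s2x

    def effect(self) -> np.ndarray:
        return self.xi


def _slice_positive(logpost, x0: float, width: float, rng,
                    max_steps: int = 50) -> float:
    """One slice-sampling update for a non-negative scalar (stepping out)."""
    x0 = max(x0, 1e-12)
    ll0 = logpost(x0)
    height = ll0 + np.log(rng.random() + 1e-300)
    lo = x0 - width * rng.random()
    hi = lo + width
    lo = max(lo, 0.0)
    for _ in range(max_steps):
        if lo <= 0.0 or logpost(lo) < height:
            break
        lo = max(lo - width, 0.0)
    for _ in range(max_steps):
        if logpost(hi) < height:
            break
        hi += width
    for _ in range(max_steps):
        x1 = lo + (hi - lo) * rng.random()
        if logpost(x1) >= height:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _interweave_G(design, spec, g_S0, y, female, rows_f, rows_m, contributions,
                  u, G, s2r, rng):
    """One ancillarity move on (G, u): resample L = chol(G) given w = L^-1 u.

    In the non-centered parameterization u = L w the records are linear in
    the three free entries of L (female record: l11 w1; male record:
    l21 w1 + l22 w2), so the likelihood conditional of (l11, l21, l22) given
    w is Gaussian and independent across the two sexes.  Proposing from it
    and accepting on the prior x Jacobian ratio leaves the posterior
    invariant while letting the scale of G jump in one move.
    """
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        return G, u
    w = sla.solve_triangular(L, u.T, lower=True, check_finite=False)  # (2, n)
    r = y - (contributions() - np.where(female, u[:, 0], u[:, 1]))

    # female block: r_f = l11 * w1 + e
    w1f = w[0, rows_f]
    prec_f = w1f @ w1f / s2r[0]
    if prec_f <= 0:
        return G, u
    mu_f = (w1f @ r[rows_f] / s2r[0]) / prec_f
    l11 = mu_f + rng.standard_normal() / np.sqrt(prec_f)
    # male block: r_m = l21 * w1 + l22 * w2 + e
    Zm = np.column_stack([w[0, rows_m], w[1, rows_m]])
    Pm = Zm.T @ Zm / s2r[1]
    try:
        c = np.linalg.cholesky(Pm)
    except np.linalg.LinAlgError:
        return G, u
    bm = Zm.T @ r[rows_m] / s2r[1]
    mu_m = sla.cho_solve((c, True), bm, check_finite=False)
    zm = rng.standard_normal(2)
    l21, l22 = mu_m + sla.solve_triangular(c, zm, lower=True, trans="T",
                                           check_finite=False)
    if l11 <= 0 or l22 <= 0:
        return G, u
    Lp = np.array([[l11, 0.0], [l21, l22]])
    Gp = Lp @ Lp.T

    def log_prior_jac(Lm, Gm):
        det = (Lm[0, 0] * Lm[1, 1]) ** 2
        tr = g_S0 * np.trace(np.linalg.inv(Gm))
        return (-(spec.g_nu + 3) / 2 * np.log(det) - 0.5 * tr
                + 2 * np.log(Lm[0, 0]) + np.log(Lm[1, 1]))

    if np.log(rng.random() + 1e-300) < log_prior_jac(Lp, Gp) - log_prior_jac(L, G):
        return Gp, (Lp @ w).T
    return G, u


def gibbs_fit(design: Design, spec: ModelSpec) -> PosteriorSamples:
    """Gibbs sampler over the mixed-model equations.

    Reproducible given ``spec.mcmc.seed``; raises on NaN/non-PSD conditionals
    with the iteration index, and on degenerate (constant) responses at
    design-build time.  Effective sample sizes are available per parameter on
    the returned object.
    """
    mc = spec.mcmc
    frames = []
    for chain in range(mc.chains):
        seed = None if mc.seed is None else (mc.seed + 7919 * chain) % (2**31)
        df = _run_chain(design, spec, np.random.default_rng(seed))
        df["chain"] = chain
        frames.append(df)
    draws = pd.concat(frames, ignore_index=True)
    meta = {
        "iterations": mc.iterations,
        "burn_in": mc.burn_in,
        "thin": mc.thin,
        "chains": mc.chains,
        "seed": mc.seed,
        "components": list(design.components),
        "n_obs": design.n,
    }
    return PosteriorSamples(draws, meta)


def _run_chain(design: Design, spec: ModelSpec, rng) -> pd.DataFrame:
    y = design.y
    female = design.female
    n = design.n
    rows_f = np.where(female)[0]
    rows_m = np.where(~female)[0]
    X = design.X_fix
    comps = design.components

    vp_f = float(np.var(y[rows_f])) if rows_f.size else float(np.var(y))
    vp_m = float(np.var(y[rows_m])) if rows_m.size else vp_f
    vp = 0.5 * (vp_f + vp_m)
    g_S0 = spec.g_scale * vp          # prior scale matrices follow the data scale
    s0_sq = spec.nu * spec.s2 * vp
    # state initialisation: half the phenotypic variance in the residual
    beta = np.zeros(X.shape[1])
    s2r = np.array([vp / 2, (np.var(y[rows_m]) if rows_m.size else vp) / 2])
    G = np.eye(2) * vp / 4
    u = np.zeros((n, 2))  # columns: female-trait, male-trait breeding values
    scalars: dict[str, _ScalarComp] = {}
    for key in ("Df", "Dm", "Xf", "Xm"):
        if key in design.kernels:
            scalars[key] = _ScalarComp(len(design.kernels[key].rows), vp / 20)
    for key in ("Y", "MEf", "MEm"):
        if key in design.groups:
            scalars[key] = _ScalarComp(design.groups[key].n_groups, vp / 20)

    def contributions() -> np.ndarray:
        eta = X @ beta
        if "Aa" in comps:
            eta = eta + np.where(female, u[:, 0], u[:, 1])
        for key, comp in scalars.items():
            if key in design.kernels:
                k = design.kernels[key]
                eta[k.rows] += comp.effect()
            else:
                g = design.groups[key]
                eta[g.rows] += comp.effect()[g.codes]
        return eta

    sex_s2 = np.where(female, s2r[0], s2r[1])
    keep = []
    mc = spec.mcmc
    fix_cols = design.fix_names
    for it in range(mc.iterations):
        sex_s2 = np.where(female, s2r[0], s2r[1])

        # --- bivariate autosomal block ---------------------------------------
        # The trait intercept is nearly collinear with the mean breeding
        # value, so beta is drawn jointly with each trait's u vector
        # ([beta, u_tr] | u_other); updating them in separate blocks mixes
        # pathologically slowly.
        if "Aa" in comps:
            p_fix = X.shape[1]
            for tr, rows, other in ((0, rows_f, 1), (1, rows_m, 0)):
                resid = y - (contributions() - X @ beta
                             - np.where(female, u[:, 0], u[:, 1]))
                # male rows still carry the conditioned-on other-trait u
                other_rows = rows_m if tr == 0 else rows_f
                resid[other_rows] -= u[other_rows, other]
                g_tt = G[tr, tr]
                g_to = G[tr, other]
                g_oo = G[other, other]
                v_cond = max(g_tt - g_to**2 / g_oo, 1e-10 * (g_tt + 1e-12))
                c = g_to / g_oo
                dim = p_fix + n
                P = np.zeros((dim, dim))
                Xw = X / sex_s2[:, None]
                P[:p_fix, :p_fix] = X.T @ Xw
                P[p_fix:, p_fix:] = design.A_inv / v_cond
                P[p_fix + rows, p_fix + rows] += 1.0 / s2r[tr]
                P[:p_fix, p_fix + rows] = Xw[rows].T
                P[p_fix + rows, :p_fix] = Xw[rows]
                b = np.zeros(dim)
                b[:p_fix] = Xw.T @ resid
                b[p_fix:] = (design.A_inv @ (c * u[:, other])) / v_cond
                b[p_fix + rows] += resid[rows] / s2r[tr]
                draw = _sample_mvn_prec(P, b, rng)
                beta = draw[:p_fix]
                u[:, tr] = draw[p_fix:]
            Sq = np.empty((2, 2))
            Au = design.A_inv @ u
            Sq[0, 0] = u[:, 0] @ Au[:, 0]
            Sq[1, 1] = u[:, 1] @ Au[:, 1]
            Sq[0, 1] = Sq[1, 0] = u[:, 0] @ Au[:, 1]
            scale = g_S0 * np.eye(2) + Sq
            G = stats.invwishart.rvs(df=spec.g_nu + n, scale=scale, random_state=rng)
            if not np.all(np.isfinite(G)):
                raise ModelError(f"non-finite autosomal covariance at iteration {it}")
            # interweaving (ancillary) move: jump the scale of G with the
            # whitened breeding values held fixed.  The conjugate update
            # above conditions on u and barely moves G; this one re-fits the
            # Cholesky factor of G to the data directly (exact Gaussian
            # likelihood conditional as proposal, Metropolis-corrected for
            # the prior and the G -> L Jacobian), which restores mixing.
            G, u = _interweave_G(design, spec, g_S0, y, female, rows_f, rows_m,
                                 contributions, u, G, s2r, rng)

        # --- scalar components ----------------------------------------------
        # The variance is updated from its *marginal* likelihood (the effect
        # vector integrated out, cheap in the kernel eigenbasis), then the
        # effect is redrawn.  Conditioning the variance on the current effect
        # would random-walk along the component-vs-residual ridge (both
        # kernels have unit-ish diagonals) and never mix.
        log_prior = (lambda s: -(spec.nu / 2 + 1) * np.log(s)
                     - s0_sq / (2 * s))
        for key, comp in scalars.items():
            if key in design.kernels:
                k = design.kernels[key]
                s2_sex = s2r[0] if key.endswith("f") else s2r[1]
                r = y[k.rows] - (contributions()[k.rows] - comp.effect())
                rt = k.U.T @ r

                def logpost(s, rt=rt, lam=k.lam, s2_sex=s2_sex):
                    v = s * lam + s2_sex
                    return -0.5 * float(np.sum(np.log(v) + rt**2 / v)) + log_prior(s)

                comp.s2x = _slice_positive(logpost, comp.s2x, vp / 10, rng)
                prec = 1.0 / s2_sex + 1.0 / (k.lam * comp.s2x)
                xi_t = (rt / s2_sex) / prec + rng.standard_normal(len(rt)) / np.sqrt(prec)
                comp.xi = k.U @ xi_t
            else:
                g = design.groups[key]
                s2_sex = s2r[1] if key in ("Y", "MEm") else s2r[0]
                r = y[g.rows] - (contributions()[g.rows] - comp.effect()[g.codes])
                counts = np.bincount(g.codes, minlength=g.n_groups)
                means = np.bincount(g.codes, weights=r, minlength=g.n_groups) / counts

                def logpost(s, means=means, counts=counts, s2_sex=s2_sex):
                    v = s + s2_sex / counts
                    return -0.5 * float(np.sum(np.log(v) + means**2 / v)) + log_prior(s)

                comp.s2x = _slice_positive(logpost, comp.s2x, vp / 10, rng)
                prec = counts / s2_sex + 1.0 / comp.s2x
                comp.xi = (counts * means / s2_sex) / prec \
                    + rng.standard_normal(g.n_groups) / np.sqrt(prec)

        # --- fixed effects (flat prior) -------------------------------------
        r = y - (contributions() - X @ beta)
        Xw = X / sex_s2[:, None]
        P = X.T @ Xw
        beta = _sample_mvn_prec(P, Xw.T @ r, rng)

        # --- residual variances ---------------------------------------------
        e = y - contributions()
        for tr, rows in ((0, rows_f), (1, rows_m)):
            if rows.size:
                ss = s0_sq + float(e[rows] @ e[rows])
                s2r[tr] = _inv_chi2(rng, spec.nu + rows.size, ss)

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            row = dict.fromkeys(PARAM_NAMES, 0.0)
            if "Aa" in comps:
                row["VA_fa"], row["VA_ma"], row["COV_Aa"] = G[0, 0], G[1, 1], G[0, 1]
            row["VD_f"] = scalars["Df"].variance if "Df" in scalars else 0.0
            row["VD_m"] = scalars["Dm"].variance if "Dm" in scalars else 0.0
            row["VA_fX"] = scalars["Xf"].variance if "Xf" in scalars else 0.0
            row["VA_mX"] = scalars["Xm"].variance if "Xm" in scalars else 0.0
            row["VA_Y"] = scalars["Y"].variance if "Y" in scalars else 0.0
            row["VME_f"] = scalars["MEf"].variance if "MEf" in scalars else 0.0
            row["VME_m"] = scalars["MEm"].variance if "MEm" in scalars else 0.0
            row["VR_f"], row["VR_m"] = s2r[0], s2r[1]
            for name, val in zip(fix_cols, beta):
                row[name] = val
            keep.append(row)
    return pd.DataFrame(keep)


# ---------------------------------------------------------------------------
# Direct-likelihood verification route
# ---------------------------------------------------------------------------

@dataclass
class MLFit:
    estimates: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    components: tuple[str, ...]


def _ml_param_list(design: Design) -> list[str]:
    names = []
    if "Aa" in design.components:
        names += ["VA_fa", "VA_ma", "rho_A"]
    for key, par in (("Df", "VD_f"), ("Dm", "VD_m"), ("Xf", "VA_fX"),
                     ("Xm", "VA_mX"), ("Y", "VA_Y"), ("MEf", "VME_f"),
                     ("MEm", "VME_m")):
        if key in design.kernels or key in design.groups:
            names.append(par)
    names += ["VR_f", "VR_m"]
    return names


def _ml_fixed_kernels(design: Design) -> dict[str, np.ndarray]:
    """Full-size covariance contribution matrix per linear parameter."""
    n = design.n
    female = design.female
    out: dict[str, np.ndarray] = {}
    for key, par in (("Df", "VD_f"), ("Dm", "VD_m"), ("Xf", "VA_fX"), ("Xm", "VA_mX")):
        if key in design.kernels:
            k = design.kernels[key]
            K = np.zeros((n, n))
            K[np.ix_(k.rows, k.rows)] = (k.U * k.lam) @ k.U.T
            out[par] = K
    for key, par in (("Y", "VA_Y"), ("MEf", "VME_f"), ("MEm", "VME_m")):
        if key in design.groups:
            g = design.groups[key]
            K = np.zeros((n, n))
            K[np.ix_(g.rows, g.rows)] = (g.codes[:, None] == g.codes[None, :])
            out[par] = K
    out["VR_f"] = np.diag(female.astype(float))
    out["VR_m"] = np.diag((~female).astype(float))
    return out


def ml_fit(design: Design, max_n: int = 1500,
           start: dict[str, float] | None = None) -> MLFit:
    """Maximize the multivariate-normal likelihood over the same covariance
    structure the Gibbs sampler uses, with fixed effects profiled out.

    The phenotypic covariance is a non-negative combination of the component
    kernels; optimization is bounded L-BFGS with analytic gradients (the
    profiled fixed effects contribute no gradient term at the GLS optimum).
    Guarded to ``max_n`` observations (dense covariance algebra).  The
    log-likelihood is full ML, comparable across nested component sets on
    identical data.  ``start`` warm-starts named parameters, which is how
    nested fits guarantee ``loglik(full) >= loglik(reduced)``.
    """
    n = design.n
    if n > max_n:
        raise ModelError(f"{n} observations exceed the dense-likelihood guard {max_n}")
    names = _ml_param_list(design)
    y = design.y
    X = design.X_fix
    female = design.female
    vp = float(np.var(y))
    fixed = _ml_fixed_kernels(design)
    has_aa = "Aa" in design.components
    if has_aa:
        ff = np.outer(female, female)
        mm = np.outer(~female, ~female)
        cross = ~(ff | mm)
        A = design.A_obs

    def nll_grad(x):
        theta = dict(zip(names, x))
        V = np.zeros((n, n))
        for par, K in fixed.items():
            V += theta[par] * K
        if has_aa:
            gf, gm = max(theta["VA_fa"], 0.0), max(theta["VA_ma"], 0.0)
            rho = theta["rho_A"]
            root = np.sqrt(gf * gm)
            M = gf * ff + gm * mm + rho * root * cross
            V += A * M
        try:
            c, low = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(len(x))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = sla.cho_solve((c, low), np.eye(n), check_finite=False)
        Vi_y = Vi @ y
        Vi_X = Vi @ X
        try:
            beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(len(x))
        e = y - X @ beta
        w = Vi @ e
        val = 0.5 * (logdet + float(e @ w) + n * np.log(2 * np.pi))
        grad = np.empty(len(x))
        for i, par in enumerate(names):
            if par in fixed:
                dV = fixed[par]
            elif par == "VA_fa":
                dV = A * (ff + (0.5 * rho * np.sqrt(gm / gf) if gf > 0 else 0.0) * cross)
            elif par == "VA_ma":
                dV = A * (mm + (0.5 * rho * np.sqrt(gf / gm) if gm > 0 else 0.0) * cross)
            else:  # rho_A
                dV = A * (root * cross)
            grad[i] = 0.5 * (np.sum(Vi * dV) - float(w @ dV @ w))
        return val, grad

    x0, lb, ub = [], [], []
    for name in names:
        if name == "rho_A":
            default = 0.3
            lb.append(-0.999)
            ub.append(0.999)
        elif name.startswith("VR"):
            default = vp / 2
            lb.append(1e-8 * vp)
            ub.append(10 * vp)
        else:
            default = vp / 8
            lb.append(1e-10 * vp)
            ub.append(10 * vp)
        x0.append(default if start is None else start.get(name, default))
    x0 = np.clip(x0, lb, ub)
    res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                            bounds=list(zip(lb, ub)),
                            options={"maxiter": 1000, "ftol": 1e-12,
                                     "gtol": 1e-8, "maxfun": 5000})
    theta = dict(zip(names, np.clip(res.x, lb, ub)))
    est = {k: float(v) for k, v in theta.items()}
    if "rho_A" in est:
        est["COV_Aa"] = est["rho_A"] * np.sqrt(est["VA_fa"] * est["VA_ma"])
    return MLFit(est, -float(res.fun), bool(res.success), n, design.components)


def lrt_component(fit_full: MLFit, fit_reduced: MLFit,
                  df_boundary: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test for variance components on the boundary.

    The statistic is ``2 * (loglik_full - loglik_reduced)``; the reference
    distribution for ``k`` boundary variances is the binomial mixture
    ``sum_j C(k,j) 2^-k chi2_j``, the 50:50 ``chi2_0 : chi2_1`` mixture when
    ``k = 1``.  Returns ``(statistic, p_value)``.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ModelError("fits are not on the same data")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -1e-6 * max(1.0, abs(fit_full.loglik)):
        raise ModelError(f"negative LRT statistic {stat:.3g}: models not nested "
                         "or reduced fit better optimized")
    stat = max(stat, 0.0)
    k = df_boundary
    if stat == 0.0:
        return 0.0, 1.0
    p = 0.0
    for j in range(k + 1):
        w = stats.binom.pmf(j, k, 0.5)
        p += w * (1.0 if j == 0 and stat <= 0 else stats.chi2.sf(stat, j) if j > 0 else 0.0)
    return float(stat), float(p)
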