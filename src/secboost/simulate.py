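"""Synthetic loci with block-LD genotypes and fixed per-variant PVE traits.

The generator reproduces the statistical structure a colocalization method
must face at a cis locus:

* **genotypes** — a latent-Gaussian copula with AR(1) correlation inside
  blocks (rho drawn per block) and independence across blocks.  Two latent
  haplotypes are thresholded at the minor-allele frequency, giving dosages
  in {0, 1, 2}.  Within-block variants are tight LD proxies of each other;
  cross-block variants are independent, mirroring the two regimes of real
  LD that proximity smoothing has to handle.
* **causal architecture** — 1-5 causal variants per locus, re-drawn until
  pairwise |LD| < 0.3 so they are approximately independent; each causal
  variant is assigned a subset of traits (its colocalization
  configuration) drawn from an empirical size distribution.
* **traits** — ``Y_l = X beta_l + eps`` with effect sizes solved so each
  causal variant explains a fixed fraction ``phi`` of the trait variance
  (the per-variant PVE); the null model sets every effect to zero.
  Residuals are independent across traits by default, or jointly Gaussian
  with an exchangeable correlation when requested.

Everything is reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, multivariate_normal

from .core import TraitDataset, LDReference, standardize

__all__ = [
    "SimTruth",
    "LocusSim",
    "DEFAULT_CONFIG_TABLE",
    "simulate_genotypes",
    "implied_dosage_correlation",
    "sample_configurations",
    "simulate_traits",
    "simulate_locus",
]

# Empirical distribution of the number of colocalized traits per causal
# variant (configuration sizes 2..10) derived from genome-wide overlap of
# fine-mapping credible sets across molecular QTL contexts.
DEFAULT_CONFIG_TABLE = {
    2: 0.380, 3: 0.285, 4: 0.163, 5: 0.079, 6: 0.051,
    7: 0.024, 8: 0.012, 9: 0.004, 10: 0.002,
}


@dataclass
class SimTruth:
    """Ground truth of one simulated locus."""

    causal: np.ndarray                 # causal variant indices
    configs: list[tuple[str, ...]]     # per-causal colocalized trait ids
    beta: dict[str, np.ndarray]        # per-trait effect vectors
    phi: dict[str, float]              # per-variant PVE by trait
    sigma_y2: dict[str, float]         # residual variances
    resid_corr: float | None           # exchangeable residual correlation
    seed: int | None

    def trait_sets(self) -> dict[int, set[str]]:
        """Map causal variant index -> set of colocalized trait ids."""
        return {int(j): set(c) for j, c in zip(self.causal, self.configs)}

    def to_dict(self) -> dict:
        return {
            "causal": [int(j) for j in self.causal],
            "configs": [list(c) for c in self.configs],
            "phi": self.phi,
            "sigma_y2": self.sigma_y2,
            "resid_corr": self.resid_corr,
            "seed": self.seed,
        }


@dataclass
class LocusSim:
    """A simulated locus: dosages, standardized trait datasets, truth."""

    dosages: np.ndarray
    variant_ids: list[str]
    datasets: list[TraitDataset]
    truth: SimTruth
    blocks: np.ndarray

    def ld(self) -> LDReference:
        """In-sample LD of the (variable) dosage columns."""
        return LDReference.from_genotypes(self.dosages, self.variant_ids)


def simulate_genotypes(N, P, n_blocks=None, rho_range=(0.6, 0.95),
                       maf_range=(0.05, 0.5), seed=None, rng=None):
    """Block-AR(1) latent-Gaussian copula dosages in {0, 1, 2}.

    Returns ``(dosages, blocks, mafs, rhos)`` where ``blocks`` labels each
    variant's LD block and ``rhos`` gives each block's latent AR(1)
    parameter.  Cross-block correlation is zero by construction.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if N < 1 or P < 1:
        raise ValueError("N and P must be positive")
    if n_blocks is None:
        n_blocks = max(P // 10, 1)
    sizes = np.full(n_blocks, P // n_blocks)
    sizes[: P % n_blocks] += 1
    rhos = rng.uniform(*rho_range, size=n_blocks)
    mafs = rng.uniform(*maf_range, size=P)
    thresholds = norm.ppf(mafs)
    blocks = np.repeat(np.arange(n_blocks), sizes)

    dosage = np.empty((N, P), dtype=np.int8)
    start = 0
    for b, (sz, rho) in enumerate(zip(sizes, rhos)):
        c = np.sqrt(1.0 - rho * rho)
        for _hap in range(2):
            eps = rng.standard_normal((N, sz))
            z = np.empty((N, sz))
            z[:, 0] = eps[:, 0]
            for j in range(1, sz):
                z[:, j] = rho * z[:, j - 1] + c * eps[:, j]
            carrier = z < thresholds[start:start + sz]
            if _hap == 0:
                dosage[:, start:start + sz] = carrier
            else:
                dosage[:, start:start + sz] += carrier
        start += sz
    return dosage, blocks, mafs, rhos


def implied_dosage_correlation(rho, maf_a, maf_b):
    """Dosage Pearson correlation implied by the latent copula.

    For two variants with latent correlation ``rho`` the dosage is the sum
    of two independent thresholded haplotypes, so its correlation equals
    the correlation of the carrier indicators.
    """
    ta, tb = norm.ppf(maf_a), norm.ppf(maf_b)
    p11 = multivariate_normal.cdf(
        [ta, tb], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    cov = p11 - maf_a * maf_b
    return cov / np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))


def sample_configurations(L, n_causal, config_table=None, seed=None,
                          rng=None, trait_ids=None, focal=None):
    """Draw one colocalization trait set per causal variant.

    The number of colocalized traits comes from ``config_table`` (a
    mapping size -> probability, truncated to the available sizes 2..L and
    renormalized); the member traits are then a uniform random subset.
    When ``focal`` is given it is always included (disease-prioritized
    design).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if trait_ids is None:
        trait_ids = [f"T{i + 1}" for i in range(L)]
    if len(trait_ids) != L:
        raise ValueError("trait_ids length must equal L")
    if L < 2:
        raise ValueError("colocalization needs at least 2 traits")
    table = dict(DEFAULT_CONFIG_TABLE if config_table is None else config_table)
    if abs(sum(table.values()) - 1.0) > 1e-6:
        raise ValueError("configuration table probabilities must sum to 1")
    sizes = np.array([s for s in sorted(table) if 2 <= s <= L])
    if sizes.size == 0:
        raise ValueError("configuration table has no feasible sizes")
    probs = np.array([table[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    configs = []
    for _ in range(n_causal):
        size = int(rng.choice(sizes, p=probs))
        if focal is not None:
            if focal not in trait_ids:
                raise ValueError("focal trait not among trait ids")
            others = [t for t in trait_ids if t != focal]
            pick = rng.choice(len(others), size=size - 1, replace=False)
            members = [focal] + [others[i] for i in sorted(pick)]
        else:
            pick = rng.choice(L, size=size, replace=False)
            members = [trait_ids[i] for i in sorted(pick)]
        configs.append(tuple(members))
    return configs


def _solve_effects(Z, causal, member_mask, phi, sigma_y2, rng,
                   tol=1e-3, max_iter=100):
    """Per-trait effects so every causal variant's PVE equals phi.

    ``Var(Y) = b^T K b + sigma_y2`` with ``K`` the in-sample correlation of
    the causal columns; each ``|b_j| = sqrt(phi * Var(Y))``.  Solved by
    fixed-point iteration on Var(Y).
    """
    idx = np.asarray(causal, dtype=np.intp)
    signs = rng.choice([-1.0, 1.0], size=idx.size)
    Zc = Z[:, idx]
    n = Z.shape[0]
    K = Zc.T @ Zc / (n - 1)
    s = signs * np.asarray(member_mask, dtype=float)
    quad = float(s @ K @ s)
    if phi * quad >= 1.0:
        raise ValueError("total requested PVE >= 1")
    var_y = sigma_y2 / (1.0 - phi * quad)
    for _ in range(max_iter):
        b = np.sqrt(phi * var_y) * s
        new = float(b @ K @ b) + sigma_y2
        if abs(new - var_y) <= tol * var_y:
            var_y = new
            break
        var_y = new
    return np.sqrt(phi * var_y) * s, var_y


def simulate_traits(X, causal, configs, phi=0.05, sigma_y2=1.0,
                    resid_corr=None, seed=None, rng=None, trait_ids=None,
                    null=False):
    """Generate phenotypes with fixed per-variant PVE at the causal variants.

    Parameters
    ----------
    X : (N, P) array
        Standardized genotype matrix.
    causal : sequence of int
        Causal variant indices (empty, or ``null=True``, for the null).
    configs : list of trait-id tuples
        Colocalized traits of each causal variant.
    phi : float or mapping trait id -> float
        Per-variant proportion of phenotypic variance explained.
    sigma_y2 : float or mapping trait id -> float
        Residual variance.
    resid_corr : float, optional
        Exchangeable residual correlation across traits (sample-overlap
        style dependence); ``None`` = independent residuals.

    Returns ``(Y, beta, truth)`` with ``Y`` of shape (N, L).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    Z = np.asarray(X, dtype=float)
    n = Z.shape[0]
    if trait_ids is None:
        trait_ids = sorted(set(t for c in configs for t in c)) or ["T1"]
    L = len(trait_ids)
    phi_map = {t: (phi[t] if isinstance(phi, dict) else float(phi))
               for t in trait_ids}
    sy2_map = {t: (sigma_y2[t] if isinstance(sigma_y2, dict)
                   else float(sigma_y2)) for t in trait_ids}
    causal = np.asarray(list(causal), dtype=np.intp)
    if null:
        causal = np.asarray([], dtype=np.intp)
        configs = []

    # residuals, optionally correlated across traits
    E = rng.standard_normal((n, L))
    if resid_corr is not None and L > 1:
        C = np.full((L, L), float(resid_corr))
        np.fill_diagonal(C, 1.0)
        E = E @ np.linalg.cholesky(C).T
    scale = np.array([np.sqrt(sy2_map[t]) for t in trait_ids])
    E = E * scale

    beta: dict[str, np.ndarray] = {}
    Y = np.empty((n, L))
    for li, tid in enumerate(trait_ids):
        b_full = np.zeros(Z.shape[1])
        if causal.size and not null and phi_map[tid] > 0:
            members = [tid in c for c in configs]
            if any(members):
                b, _ = _solve_effects(Z, causal, members, phi_map[tid],
                                      sy2_map[tid], rng)
                b_full[causal] = b
        beta[tid] = b_full
        Y[:, li] = Z[:, causal] @ b_full[causal] + E[:, li] \
            if causal.size else E[:, li]
    truth = SimTruth(
        causal=causal,
        configs=list(configs),
        beta=beta,
        phi=phi_map,
        sigma_y2=sy2_map,
        resid_corr=resid_corr,
        seed=None,
    )
    return Y, beta, truth


def _draw_causal(Z, n_causal, rng, max_ld=0.3, max_tries=200):
    """Draw approximately independent causal variants (pairwise |LD| < max_ld)."""
    n, P = Z.shape
    for _ in range(max_tries):
        idx = np.sort(rng.choice(P, size=n_causal, replace=False))
        C = Z[:, idx].T @ Z[:, idx] / (n - 1)
        off = np.abs(C[np.triu_indices(n_causal, k=1)])
        if off.size == 0 or off.max() < max_ld:
            return idx
    raise RuntimeError("could not draw independent causal variants")


def simulate_locus(N=1100, P=1000, L=5, n_causal=1, phi=0.05, seed=None,
                   n_blocks=None, rho_range=(0.6, 0.95),
                   maf_range=(0.05, 0.5), sigma_y2=1.0, resid_corr=None,
                   config_table=None, trait_ids=None, focal=None,
                   null=False, null_sigma_range=(0.1, 1.0)):
    """One simulated locus end to end.

    In the null mode all effects are zero and each trait's residual
    variance is drawn uniformly from ``null_sigma_range``.
    ``phi`` may be a mapping trait id -> PVE (e.g. a weaker focal trait).
    """
    rng = np.random.default_rng(seed)
    if trait_ids is None:
        trait_ids = [f"T{i + 1}" for i in range(L)]
    dosage, blocks, mafs, rhos = simulate_genotypes(
        N, P, n_blocks=n_blocks, rho_range=rho_range, maf_range=maf_range,
        rng=rng)
    Z, kept = standardize(dosage)  # monomorphic draws are dropped
    variant_ids = [f"v{j + 1}" for j in kept]

    if null:
        sig = {t: float(rng.uniform(*null_sigma_range)) for t in trait_ids}
        Y, beta, truth = simulate_traits(
            Z, [], [], phi=0.0, sigma_y2=sig, resid_corr=resid_corr,
            rng=rng, trait_ids=trait_ids, null=True)
    else:
        causal = _draw_causal(Z, n_causal, rng)
        if L == 2:
            configs = [tuple(trait_ids)] * n_causal
        else:
            configs = sample_configurations(
                L, n_causal, config_table=config_table, rng=rng,
                trait_ids=trait_ids, focal=focal)
        Y, beta, truth = simulate_traits(
            Z, causal, configs, phi=phi, sigma_y2=sigma_y2,
            resid_corr=resid_corr, rng=rng, trait_ids=trait_ids)
    truth.seed = seed

    datasets = []
    for li, tid in enumerate(trait_ids):
        y = Y[:, li]
        sd = y.std(ddof=1)
        datasets.append(TraitDataset(tid, (y - y.mean()) / sd, Z, variant_ids))
    return LocusSim(
        dosages=dosage[:, kept],
        variant_ids=variant_ids,
        datasets=datasets,
        truth=truth,
        blocks=blocks[kept],
    )
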