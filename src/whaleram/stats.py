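"""Probabilistic comparison of model variants.

Material-property uncertainty is propagated by Monte Carlo: each iteration
independently draws the three tissue Young's moduli (skull, connective
tissue, oil/wax) from a normal distribution centred on the nominal value
with a coefficient of variation of 10% (truncated at zero by resampling),
re-solves the static problem and stores the element-wise von Mises field.

Two such populations are compared element by element with the standardised
mean-difference statistic

    z_i = (mean_B,i - mean_A,i) / (0.5 * (sd_A,i + sd_B,i)),

and its significance is assessed by a paired label-permutation test: random
subsets of iteration pairs have their A/B labels exchanged, z is recomputed,
and the per-element 99th percentile of the permuted values is the
significance threshold (alpha = 0.01, one-sided: elements where the observed
z exceeds it are flagged).  Standard deviations are sample (n-1) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fem import (
    DEFAULT_MATERIALS,
    DEFAULT_THICKNESS,
    BoundaryConditions,
    LinearSystem,
    Material,
    MATERIAL_GROUPS,
    StiffnessDecomposition,
    StressField,
)
from .geometry import Mesh

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StressPopulation:
    """Monte Carlo population of element-wise von Mises stress.

    ``von_mises`` is (n_iter, n_elements) in Pa; ``moduli`` the sampled
    Young's moduli (n_iter, n_groups) with ``group_names`` giving the column
    order; ``seed`` the RNG seed that generated the population.
    """

    von_mises: np.ndarray
    moduli: np.ndarray
    group_names: tuple[str, ...]
    seed: int | None
    n_resampled: int = 0

    @property
    def n_iter(self) -> int:
        return self.von_mises.shape[0]

    @property
    def n_elements(self) -> int:
        return self.von_mises.shape[1]

    def mean(self) -> np.ndarray:
        return self.von_mises.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.von_mises.std(axis=0, ddof=1)


@dataclass(frozen=True)
class ZField:
    """Element-wise z statistic with its permutation significance threshold.

    ``valid`` marks elements whose z is finite (a zero pooled standard
    deviation with unequal means yields +-inf, which is flagged and excluded
    from thresholding); ``significant`` is True exactly where a valid z
    exceeds its threshold.
    """

    z: np.ndarray
    threshold: np.ndarray
    significant: np.ndarray
    valid: np.ndarray
    n_perm: int
    percentile: float

    def significant_fraction(self) -> float:
        """Fraction of valid elements exceeding their threshold."""
        n = int(self.valid.sum())
        return float(self.significant.sum()) / n if n else float("nan")


def sample_moduli(
    nominal: dict[str, float],
    n_iter: int,
    cv: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Draw (n_iter, n_groups) Young's moduli ~ N(nominal, cv*nominal),
    truncated at > 0 by resampling.  Returns the draws and the resample
    count."""
    names = list(nominal)
    nom = np.array([nominal[g] for g in names])
    draws = rng.normal(nom, cv * nom, size=(n_iter, len(names)))
    n_resampled = 0
    bad = draws <= 0
    while bad.any():
        n_resampled += int(bad.sum())
        draws[bad] = rng.normal(
            np.broadcast_to(nom, draws.shape)[bad],
            cv * np.broadcast_to(nom, draws.shape)[bad],
        )
        bad = draws <= 0
    return draws, n_resampled


def run_monte_carlo(
    mesh: Mesh,
    load_case,
    n_iter: int,
    cv: float = 0.10,
    seed: int | None = None,
    materials: dict[str, Material] | None = None,
    groups: dict[str, tuple[str, ...]] | None = None,
    bcs: BoundaryConditions | None = None,
    thickness: float = DEFAULT_THICKNESS,
) -> StressPopulation:
    """Monte Carlo propagation of tissue-stiffness uncertainty.

    Each iteration draws the group Young's moduli, re-solves the static
    problem and stores the element-wise von Mises field.  Identical seeds
    give bit-identical populations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 <= cv < 1:
        raise ValueError(f"cv must be in [0, 1), got {cv}")
    materials = materials or DEFAULT_MATERIALS
    groups = groups or MATERIAL_GROUPS
    bcs = bcs or BoundaryConditions.fix_segment(mesh, "posterior")

    decomp = StiffnessDecomposition(mesh, materials, groups, thickness)
    system = LinearSystem(decomp, bcs)
    f = load_case.nodal_forces(mesh)
    names = tuple(decomp.groups)
    nominal = {g: decomp.nominal[g] for g in names}

    rng = np.random.default_rng(seed)
    if cv == 0:
        draws = np.tile([nominal[g] for g in names], (n_iter, 1))
        n_resampled = 0
    else:
        draws, n_resampled = sample_moduli(nominal, n_iter, cv, rng)
        if n_resampled:
            log.info("resampled %d non-positive modulus draws", n_resampled)

    # precompute stress-recovery structure once: per-label selections,
    # unit-modulus constitutive matrices, and the group of each label
    from .fem import _b_matrices

    B, _ = _b_matrices(mesh)
    label_of_group = {
        lab: g for g, labs in decomp.groups.items() for lab in labs
    }
    labels = [lab for lab in np.unique(mesh.element_material)]
    sels = {lab: mesh.element_material == lab for lab in labels}
    dhats = {
        lab: Material(1.0, materials[lab].nu).d_matrix() for lab in labels
    }
    group_idx = {g: k for k, g in enumerate(names)}

    vm = np.empty((n_iter, mesh.n_elements))
    stress = np.empty((mesh.n_elements, 3))
    for it in range(n_iter):
        moduli = dict(zip(names, draws[it]))
        u, _ = system.solve(f, moduli)
        ue = u.reshape(-1, 2)[mesh.triangles].reshape(mesh.n_elements, 6)
        strain = np.einsum("eij,ej->ei", B, ue)
        for lab in labels:
            sel = sels[lab]
            e_lab = draws[it, group_idx[label_of_group[lab]]]
            stress[sel] = (strain[sel] @ dhats[lab].T) * e_lab
        vm[it] = np.sqrt(
            stress[:, 0] ** 2
            - stress[:, 0] * stress[:, 1]
            + stress[:, 1] ** 2
            + 3 * stress[:, 2] ** 2
        )
    return StressPopulation(
        von_mises=vm,
        moduli=draws,
        group_names=names,
        seed=seed,
        n_resampled=n_resampled,
    )


def _z_from_matrices(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z per element from (n_iter, E) matrices; inf where pooled sd is zero
    but means differ, 0 where both vanish."""
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    sd = 0.5 * (a.std(axis=0, ddof=1) + b.std(axis=0, ddof=1))
    num = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / sd
        z = np.where((sd == 0) & (num == 0), 0.0, z)
        z = np.where((sd == 0) & (num != 0), np.sign(num) * np.inf, z)
    return z


def elemental_z(pop_a: StressPopulation, pop_b: StressPopulation) -> np.ndarray:
    """Standardised per-element mean difference (B minus A)."""
    if pop_a.n_elements != pop_b.n_elements:
        raise ValueError("populations are on different meshes")
    return _z_from_matrices(pop_a.von_mises, pop_b.von_mises)


def _permutation_masks(
    n_iter: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_masks, n_iter) boolean label-swap patterns.

    If the requested number of permutations reaches the 2^n_iter distinct
    pair relabellings, they are enumerated exactly instead of sampled.
    When sampling, the identity labelling is always included, which keeps
    the Monte Carlo permutation test valid (never anticonservative).
    """
    if n_iter < 63 and n_perm >= 2**n_iter:
        patterns = np.arange(2**n_iter, dtype=np.uint64)
        bits = (patterns[:, None] >> np.arange(n_iter, dtype=np.uint64)) & 1
        return bits.astype(bool)
    masks = rng.random((n_perm, n_iter)) < 0.5
    masks[0] = False
    return masks


def _permuted_z(a: np.ndarray, b: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """z fields for a batch of label-swap masks, via sufficient statistics.

    Swapping pair i changes the per-element sums by +-(b_i - a_i) and the
    sums of squares by +-(b_i^2 - a_i^2); means and sample standard
    deviations for every mask then follow from two mask-by-data matrix
    products, avoiding materialising permuted populations.
    """
    n, n_elem = a.shape
    M = masks.astype(float)
    # centre on the pooled per-element mean: sds and mean differences are
    # unchanged and the sum-of-squares update loses no precision
    c = (a.sum(0) + b.sum(0)) / (2 * n)
    a = a - c
    b = b - c
    d = b - a
    d2 = b**2 - a**2
    sum_a, sum_b = a.sum(0), b.sum(0)
    sq_a, sq_b = (a**2).sum(0), (b**2).sum(0)
    swap = M @ d          # (B, E): sum of swapped pair differences
    swap2 = M @ d2
    mean_a = (sum_a + swap) / n
    mean_b = (sum_b - swap) / n
    # sample variances from updated sums of squares
    var_a = ((sq_a + swap2) - n * mean_a**2) / (n - 1)
    var_b = ((sq_b - swap2) - n * mean_b**2) / (n - 1)
    np.clip(var_a, 0.0, None, out=var_a)  # guard fp cancellation
    np.clip(var_b, 0.0, None, out=var_b)
    sd = 0.5 * (np.sqrt(var_a) + np.sqrt(var_b))
    num = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / sd
        z = np.where((sd == 0) & (num == 0), 0.0, z)
        z = np.where((sd == 0) & (num != 0), np.sign(num) * np.inf, z)
    return z


def permutation_threshold(
    pop_a: StressPopulation,
    pop_b: StressPopulation,
    n_perm: int = 10_000,
    percentile: float = 99.0,
    seed: int | None = None,
) -> ZField:
    """Paired label-permutation significance threshold for the z field.

    For each permutation a random subset of iteration pairs exchanges its
    A/B labels and z is recomputed; the per-element ``percentile`` of the
    permuted z values is the significance threshold, and elements whose
    observed z exceeds it are flagged.
    """
    if pop_a.n_iter != pop_b.n_iter:
        raise ValueError("paired permutation requires equal n_iter")
    a, b = pop_a.von_mises, pop_b.von_mises
    z_obs = _z_from_matrices(a, b)
    valid = np.isfinite(z_obs)
    if not valid.all():
        log.info("%d elements with infinite z excluded from thresholding",
                 int((~valid).sum()))

    rng = np.random.default_rng(seed)
    masks = _permutation_masks(pop_a.n_iter, n_perm, rng)
    zperm = _permuted_z(a, b, masks)
    with np.errstate(invalid="ignore"):
        threshold = np.nanpercentile(
            np.where(np.isfinite(zperm), zperm, np.nan), percentile, axis=0
        )
    significant = valid & np.isfinite(threshold) & (z_obs > threshold)
    return ZField(
        z=z_obs,
        threshold=threshold,
        significant=significant,
        valid=valid & np.isfinite(threshold),
        n_perm=len(masks),
        percentile=percentile,
    )
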