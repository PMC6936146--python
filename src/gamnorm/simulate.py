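"""Synthetic GAM experiments with known ground truth.

The generative model mirrors the GAM protocol geometrically: each nuclear
profile (NP) is one thin slab cut at a random orientation through one
nucleus, and a genomic bin is detected when its 3D position falls inside
the slab and an independent per-bin detection-efficiency coin succeeds.
Chromosomes are confined random-walk polymers inside a spherical nucleus,
so 3D distance grows with genomic separation up to the confinement
plateau and co-segregation frequency decays with 3D distance — the two
features the raw-contact construction relies on. A fresh, independently
folded nucleus is generated for every NP, matching GAM's one-slice-per-
nucleus design.

Detection-efficiency bias is injected by shaping the per-bin success
probability p_i (uniform, a linear gradient along the genome, or coupled
to a GC track), which creates the window-detection-frequency and
fragment-length bias structure that the normalization methods are meant
to remove. All outputs are bit-reproducible given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .binning import GenomeBinning
from .types import BiasTrack, ContactMatrix, CosegregationMatrix

__all__ = [
    "NucleusModel",
    "SliceSpec",
    "simulate_nucleus",
    "slice_nucleus",
    "ground_truth_proximity",
    "inject_detection_bias",
    "random_cosegregation",
]


@dataclass(frozen=True)
class NucleusModel:
    """One folded nucleus: a confined random-walk polymer per chromosome.

    ``coordinates`` holds one 3D point per bin (arbitrary length units),
    all inside a sphere of radius ``radius``; consecutive bins of a
    chromosome sit at distance ``bond_length``.
    """

    binning: GenomeBinning
    coordinates: np.ndarray  # (total_bins, 3)
    radius: float
    bond_length: float
    seed: int


@dataclass(frozen=True)
class SliceSpec:
    """Slicing protocol: how many NPs, how thick a slab, how efficient
    the detection."""

    n_nps: int
    thickness: float
    efficiency: float | np.ndarray = 1.0  # scalar or per-bin p_i in (0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nps < 1:
            raise ValueError("need at least one nuclear profile")
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")
        p = np.asarray(self.efficiency, dtype=float)
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("detection efficiency must lie in (0, 1]")

    def efficiency_vector(self, n_bins: int) -> np.ndarray:
        p = np.asarray(self.efficiency, dtype=float)
        if p.ndim == 0:
            return np.full(n_bins, float(p))
        if p.shape != (n_bins,):
            raise ValueError(f"efficiency length {p.shape} != {n_bins} bins")
        return p.copy()

    def efficiency_track(self, binning: GenomeBinning) -> BiasTrack:
        """The injected per-bin detection efficiency as a bias track."""
        return BiasTrack(binning, "detection_efficiency",
                         self.efficiency_vector(binning.total_bins))


def _confined_walk(n: int, radius: float, bond: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random walk of n beads with fixed bond length inside a sphere."""
    pts = np.empty((n, 3))
    # start uniformly inside the sphere
    while True:
        p = rng.uniform(-radius, radius, 3)
        if p @ p <= radius ** 2:
            pts[0] = p
            break
    for i in range(1, n):
        for _ in range(1000):
            step = rng.normal(size=3)
            step *= bond / np.linalg.norm(step)
            cand = pts[i - 1] + step
            if cand @ cand <= radius ** 2:
                pts[i] = cand
                break
        else:
            raise ValueError(
                "confinement infeasible: no admissible step found "
                f"(radius={radius}, bond_length={bond})")
    return pts


def simulate_nucleus(binning: GenomeBinning, radius: float = 1.0,
                     bond_length: float = 0.08, seed: int = 0) -> NucleusModel:
    """Fold one nucleus: an independent confined random walk per
    chromosome, deterministic given the seed."""
    if not (radius > bond_length > 0):
        raise ValueError("require radius > bond_length > 0")
    rng = np.random.default_rng(seed)
    coords = np.empty((binning.total_bins, 3))
    for chrom in binning.chromosomes:
        sl = binning.chrom_slice(chrom)
        coords[sl] = _confined_walk(sl.stop - sl.start, radius,
                                    bond_length, rng)
    return NucleusModel(binning, coords, radius, bond_length, seed)


def slice_nucleus(model: NucleusModel, spec: SliceSpec) -> CosegregationMatrix:
    """Cut one random slab per NP, each through a freshly folded nucleus.

    The slab has a uniformly random orientation (unit normal uniform on
    the sphere) and a uniformly random offset along that normal within
    [-radius, radius], so partial edge slabs occur naturally. A bin is
    detected iff its bead lies inside the slab and a Bernoulli(p_i) coin
    succeeds.
    """
    binning = model.binning
    n = binning.total_bins
    p = spec.efficiency_vector(n)
    half = spec.thickness / 2.0
    detection = np.zeros((n, spec.n_nps), dtype=np.uint8)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_nps)
    for j in range(spec.n_nps):
        rng = np.random.default_rng(children[j])
        nucleus = np.empty((n, 3))
        for chrom in binning.chromosomes:
            sl = binning.chrom_slice(chrom)
            nucleus[sl] = _confined_walk(sl.stop - sl.start, model.radius,
                                         model.bond_length, rng)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        offset = rng.uniform(-model.radius, model.radius)
        in_slab = np.abs(nucleus @ normal - offset) <= half
        coin = rng.random(n) < p
        detection[:, j] = (in_slab & coin).astype(np.uint8)
    np_ids = tuple(f"NP{j + 1}" for j in range(spec.n_nps))
    return CosegregationMatrix(binning, np_ids, detection)


def ground_truth_proximity(model: NucleusModel,
                           chromosome: str | None = None) -> ContactMatrix:
    """True proximity matrix 1 / (1 + d_ij) from the model's coordinates
    (cis, one chromosome)."""
    binning = model.binning
    if chromosome is None:
        if len(binning.chromosomes) != 1:
            raise ValueError("specify a chromosome for multi-chromosome models")
        chromosome = binning.chromosomes[0]
    pts = model.coordinates[binning.chrom_slice(chromosome)]
    d = squareform(pdist(pts))
    return ContactMatrix(binning, chromosome, 1.0 / (1.0 + d),
                         provenance="ground_truth")


def inject_detection_bias(spec: SliceSpec, binning: GenomeBinning,
                          profile: str = "linear_gradient",
                          strength: float = 0.5,
                          gc: BiasTrack | None = None) -> SliceSpec:
    """Shape the per-bin detection efficiency to inject systematic bias.

    ``uniform`` leaves p unchanged; ``linear_gradient`` scales p linearly
    from p0*(1 - strength) at the first bin to p0 at the last;
    ``gc_coupled`` makes p affine in the (min-max scaled) GC content,
    spanning the same range. ``strength`` in [0, 1).
    """
    if not (0 <= strength < 1):
        raise ValueError("strength must lie in [0, 1)")
    n = binning.total_bins
    p0 = spec.efficiency_vector(n)
    if profile == "uniform":
        shaped = p0
    elif profile == "linear_gradient":
        ramp = np.linspace(1.0 - strength, 1.0, n)
        shaped = p0 * ramp
    elif profile == "gc_coupled":
        if gc is None:
            raise ValueError("gc_coupled profile requires a GC bias track")
        g = gc.values.astype(float)
        finite = np.isfinite(g)
        lo, hi = g[finite].min(), g[finite].max()
        scaled = np.where(finite, (g - lo) / (hi - lo) if hi > lo else 1.0, 1.0)
        shaped = p0 * (1.0 - strength * (1.0 - scaled))
    else:
        raise ValueError(f"unknown bias profile {profile!r}")
    return replace(spec, efficiency=shaped)


def random_cosegregation(binning: GenomeBinning, n_nps: int,
                         detection_rate: float = 0.1,
                         mean_fragment_length: float = 3.0,
                         seed: int = 0) -> CosegregationMatrix:
    """Structureless co-segregation table with geometric fragment lengths.

    Each NP column is a two-state Markov chain along the genome whose
    stationary detected fraction is ``detection_rate`` and whose detected
    runs have mean length ``mean_fragment_length`` (geometric). Useful for
    bias-distribution tests where only run-length structure matters, not
    3D geometry.
    """
    if not (0 < detection_rate < 1):
        raise ValueError("detection_rate must lie in (0, 1)")
    if mean_fragment_length < 1:
        raise ValueError("mean fragment length must be >= 1")
    rng = np.random.default_rng(seed)
    q_leave = 1.0 / mean_fragment_length  # P(detected -> undetected)
    # stationarity: rate = q_enter / (q_enter + q_leave)
    q_enter = q_leave * detection_rate / (1.0 - detection_rate)
    det = np.zeros((binning.total_bins, n_nps), dtype=np.uint8)
    for chrom in binning.chromosomes:
        sl = binning.chrom_slice(chrom)
        nb = sl.stop - sl.start
        u = rng.random((nb, n_nps))
        block = np.zeros((nb, n_nps), dtype=np.uint8)
        block[0] = u[0] < detection_rate
        for i in range(1, nb):
            stay = block[i - 1] == 1
            block[i] = np.where(stay, u[i] < 1 - q_leave, u[i] < q_enter)
        det[sl] = block
    np_ids = tuple(f"NP{j + 1}" for j in range(n_nps))
    return CosegregationMatrix(binning, np_ids, det)
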