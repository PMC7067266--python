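"""Synthetic molecular geometries with a smooth geometry→NMR oracle.

Real training labels for this method come from quantum-chemical
calculations on crystal-structure geometries; neither is bundled here.
This module generates randomized, chemically plausible 3-D clusters and
labels them with a smooth, deterministic function of interatomic distances
and angles — the same information content the representations encode — so
learning curves, ensemble-spread behaviour and adaptive sampling can be
exercised end to end.  The oracle makes no claim to emulate quantum
chemistry; it emulates the *statistical* structure the method assumes:
a smooth mapping from local geometry to parameter values, element
heterogeneity across molecules, and optional Gaussian label noise.

Geometry model: a random tree of 4–12 heavy atoms (C/N/O/F by regime
weights, first atom always carbon) with bond lengths 1.2–1.6 Å and
jittered tetrahedral-ish branching; hydrogens fill carbon valence at
~1.09 Å.  A minimum interatomic distance of 0.9 Å is enforced by rejection.

Label oracle: each atom carries a latent environment score
u_i = Σ_{j≠i} w(elem_j)·Z_j·exp(−r_ij/decay_length), squashed into [0, 1)
by squash(u) = u/(u_scale + u).  The element weights w give fluorine an
outsized pull (its strong electronegativity effects on shielding are the
real-data analogue), so molecules from a fluorine-rich regime occupy a
latent region that a training set without them never visits — the
heterogeneity that makes ensemble spread informative and adaptive
sampling worthwhile.  Shift labels are base + range·squash(u);
one-bond C–H coupling labels are base + range·g(r_CH, ā) with
g = 0.5·clip((1.19 − r_CH)/0.2, 0, 1) + 0.5·(ā/π), ā the cosine-cutoff
weighted mean angle H–C–X over the carbon's other neighbours within
1.8 Å (0.5 replaces ā/π when there are none), so g is smooth in every
coordinate.  Bonds for coupling labels are C–H pairs closer
than 1.2 Å, fixed at generation time and recorded in the labels so
downstream code never re-derives bonding.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .structures import ATOMIC_NUMBERS, Dataset, LabelRecord, Structure

__all__ = [
    "OracleParams",
    "GenerationError",
    "DEFAULT_REGIME",
    "FLUORINE_REGIME",
    "gen_structures",
    "oracle_labels",
    "label_dataset",
    "make_benchmark",
    "two_regime_benchmark",
]

#: Heavy-atom element weights of the common organic regime (C/N/O, no F).
DEFAULT_REGIME: dict[str, float] = {"C": 0.7, "N": 0.1, "O": 0.2, "F": 0.0}

#: Rare regime rich in fluorine — the canonical heterogeneity fixture for
#: adaptive-sampling and variance-filter behaviour.
FLUORINE_REGIME: dict[str, float] = {"C": 0.5, "N": 0.0, "O": 0.1, "F": 0.4}

#: C–H pairs closer than this (Å) are bonded at generation time.
BOND_CH_CUTOFF = 1.2
#: Neighbour cutoff (Å) for the coupling oracle's mean-angle term.
NEIGHBOR_CUTOFF = 1.8


class GenerationError(RuntimeError):
    """The rejection-sampling budget was exhausted (pathological spec)."""


@dataclass(frozen=True)
class OracleParams:
    """Parameters of the synthetic label oracle.

    ``base_range`` maps each parameter to (base, range) in its natural
    unit, landing labels in realistic intervals: ¹H shifts ~0–10 ppm,
    ¹³C shifts ~0–200 ppm, ¹J_CH couplings ~100–250 Hz.  ``noise_sd``
    (same units) defaults to zero because the oracle stands in for
    deterministic quantum-chemical labels; set it positive to study noise
    floors.
    """

    decay_length: float = 2.0  # Å
    u_scale: float = 25.0
    element_weights: dict[str, float] = field(default_factory=lambda: {
        "H": 1.0, "C": 1.0, "N": 1.0, "O": 1.0, "F": 3.0,
    })
    base_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "shift_1H": (0.0, 10.0),
        "shift_13C": (0.0, 200.0),
        "j1_CH": (100.0, 150.0),
    })
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "shift_1H": 0.0, "shift_13C": 0.0, "j1_CH": 0.0,
    })
    seed: int = 0

    def __post_init__(self):
        if self.decay_length <= 0 or self.u_scale <= 0:
            raise ValueError("decay_length and u_scale must be positive")
        for p, (b, r) in self.base_range.items():
            if r <= 0:
                raise ValueError(f"range for {p} must be positive")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")
        if any(w <= 0 for w in self.element_weights.values()):
            raise ValueError("element weights must be positive")


def _squash(u: np.ndarray | float, u_scale: float):
    return u / (u_scale + u)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _min_dist_ok(pos: np.ndarray, placed: list[np.ndarray]) -> bool:
    return all(np.linalg.norm(pos - q) >= 0.9 for q in placed)


def _gen_one(rng: np.random.Generator, sid: str, weights: dict[str, float],
             budget: int = 500) -> Structure:
    elems = [e for e, w in weights.items() if w > 0]
    probs = np.array([weights[e] for e in elems])
    probs = probs / probs.sum()

    n_heavy = int(rng.integers(4, 13))
    heavy_elems = ["C"] + [str(rng.choice(elems, p=probs)) for _ in range(n_heavy - 1)]
    positions: list[np.ndarray] = [np.zeros(3)]
    parents: list[int] = [-1]

    for k in range(1, n_heavy):
        placed = False
        for _ in range(budget):
            parent = int(rng.integers(0, k))
            length = rng.uniform(1.2, 1.6)
            direction = _random_unit(rng)
            pos = positions[parent] + length * direction
            # tetrahedral-ish branching: keep bond angles at the parent open
            ok_angle = True
            for j in range(k):
                if parents[j] == parent or j == parents[parent]:
                    v1 = pos - positions[parent]
                    v2 = positions[j] - positions[parent]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if cosang > np.cos(np.deg2rad(80)):
                        ok_angle = False
                        break
            if ok_angle and _min_dist_ok(pos, positions):
                positions.append(pos)
                parents.append(parent)
                placed = True
                break
        if not placed:
            raise GenerationError(f"{sid}: heavy-atom placement budget exhausted")

    elements = list(heavy_elems)
    coords = list(positions)
    heavy_degree = [0] * n_heavy
    for k in range(1, n_heavy):
        heavy_degree[k] += 1
        heavy_degree[parents[k]] += 1

    for c in range(n_heavy):
        if heavy_elems[c] != "C":
            continue
        for _ in range(max(0, 4 - heavy_degree[c])):
            placed = False
            for _ in range(budget):
                length = rng.normal(1.09, 0.02)
                pos = coords[c] + length * _random_unit(rng)
                if _min_dist_ok(pos, coords):
                    elements.append("H")
                    coords.append(pos)
                    placed = True
                    break
            if not placed:
                raise GenerationError(f"{sid}: hydrogen placement budget exhausted")

    return Structure(sid, tuple(elements), np.array(coords))


def gen_structures(n: int, regime: dict[str, float] | None = None,
                   seed: int = 0, id_prefix: str = "mol") -> list[Structure]:
    """Generate ``n`` randomized plausible clusters; deterministic given seed.

    ``regime`` gives heavy-atom element weights (C/N/O/F); the first heavy
    atom is always carbon so every molecule has C–H environments.  A
    structure whose rejection budget is exhausted is retried with fresh
    randomness a bounded number of times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = dict(DEFAULT_REGIME if regime is None else regime)
    bad = set(weights) - {"C", "N", "O", "F"}
    if bad:
        raise ValueError(f"regime may only weight C/N/O/F, got {sorted(bad)}")
    if weights.get("C", 0) <= 0:
        raise ValueError("regime must give carbon positive weight")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        sid = f"{id_prefix}_{k:05d}"
        for attempt in range(50):
            try:
                out.append(_gen_one(rng, sid, weights))
                break
            except GenerationError:
                if attempt == 49:
                    raise
    return out


def perturb_structure(s: Structure, sigma: float, seed: int = 0,
                      new_id: str | None = None, budget: int = 200) -> Structure:
    """A geometric decoy: every coordinate jittered by N(0, sigma) Å.

    Redraws (up to ``budget`` times) when the jitter collapses two atoms
    below the validity floor.  Used to fabricate wrong candidate
    structures for discrimination tests.
    """
    rng = np.random.default_rng(seed)
    for _ in range(budget):
        coords = s.coords + rng.normal(0.0, sigma, size=s.coords.shape)
        try:
            return Structure(new_id or f"{s.id}_p{sigma:g}", s.elements, coords)
        except Exception:
            continue
    raise GenerationError(f"could not perturb {s.id} at sigma={sigma}")


def _latents(s: Structure, p: OracleParams) -> np.ndarray:
    z = s.atomic_numbers * np.array([p.element_weights[e] for e in s.elements])
    r = s.distance_matrix()
    w = np.exp(-r / p.decay_length)
    np.fill_diagonal(w, 0.0)
    return w @ z


def bonded_ch_pairs(s: Structure) -> list[tuple[int, int]]:
    """(carbon, hydrogen) index pairs closer than the generation-time bond cutoff."""
    r = s.distance_matrix()
    pairs = []
    for c in range(s.n_atoms):
        if s.elements[c] != "C":
            continue
        for h in range(s.n_atoms):
            if s.elements[h] == "H" and r[c, h] < BOND_CH_CUTOFF:
                pairs.append((c, h))
    return pairs


def oracle_labels(s: Structure, p: OracleParams) -> list[LabelRecord]:
    """Deterministic oracle labels for every H, C, and bonded C–H pair.

    Noise, when enabled, is drawn from a generator seeded by
    (p.seed, crc32(structure id)) so labels do not depend on call order.
    """
    rng = np.random.default_rng([p.seed, zlib.crc32(s.id.encode())])
    u = _latents(s, p)
    sq = _squash(u, p.u_scale)
    r = s.distance_matrix()
    records: list[LabelRecord] = []

    for param, elem in (("shift_1H", "H"), ("shift_13C", "C")):
        base, rng_w = p.base_range[param]
        sd = p.noise_sd[param]
        for i in range(s.n_atoms):
            if s.elements[i] != elem:
                continue
            val = base + rng_w * sq[i]
            if sd > 0:
                val += rng.normal(0.0, sd)
            records.append(LabelRecord(s.id, param, (i,), float(val)))

    base_j, range_j = p.base_range["j1_CH"]
    sd_j = p.noise_sd["j1_CH"]
    for c, h in bonded_ch_pairs(s):
        neigh = [j for j in range(s.n_atoms)
                 if j not in (c, h) and r[c, j] < NEIGHBOR_CUTOFF]
        if neigh:
            vh = s.coords[h] - s.coords[c]
            angs, wts = [], []
            for j in neigh:
                vj = s.coords[j] - s.coords[c]
                cosang = vh @ vj / (np.linalg.norm(vh) * np.linalg.norm(vj))
                angs.append(np.arccos(np.clip(cosang, -1.0, 1.0)))
                # smooth cosine weight so the mean angle is continuous as
                # neighbours cross the cutoff
                wts.append(0.5 * (np.cos(np.pi * r[c, j] / NEIGHBOR_CUTOFF) + 1.0))
            t_a = float(np.average(angs, weights=wts)) / np.pi
        else:
            t_a = 0.5
        t_r = float(np.clip((1.19 - r[c, h]) / 0.2, 0.0, 1.0))
        val = base_j + range_j * np.clip(0.5 * t_r + 0.5 * t_a, 0.0, 1.0)
        if sd_j > 0:
            val += rng.normal(0.0, sd_j)
        records.append(LabelRecord(s.id, "j1_CH", (c, h), float(val)))
    return records


def label_dataset(structures, p: OracleParams) -> Dataset:
    labels = []
    for s in structures:
        labels.extend(oracle_labels(s, p))
    return Dataset(structures={s.id: s for s in structures}, labels=labels)


def make_benchmark(
    n_superset: int,
    n_heldout: int,
    oracle: OracleParams | None = None,
    regimes: list[tuple[dict[str, float], float]] | None = None,
    seed: int = 0,
) -> tuple[Dataset, Dataset, dict]:
    """Disjoint (superset, held-out) datasets plus a manifest.

    ``regimes`` is a list of (element-weight dict, fraction); structure
    counts per regime follow exact largest-remainder apportionment, so the
    emitted proportions match the requested fractions to rounding.  Structure ids are
    prefixed ``s``/``h`` and are disjoint by construction.
    """
    oracle = oracle or OracleParams()
    regimes = regimes or [(DEFAULT_REGIME, 1.0)]
    total = sum(f for _, f in regimes)
    fracs = [f / total for _, f in regimes]

    def apportion(n: int) -> list[int]:
        raw = [n * f for f in fracs]
        counts = [int(np.floor(x)) for x in raw]
        rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
        for i in rema[: n - sum(counts)]:
            counts[i] += 1
        return counts

    def build(n: int, prefix: str, sub_seed: int):
        structures = []
        counts = apportion(n)
        offset = 0
        for ri, ((weights, _), cnt) in enumerate(zip(regimes, counts)):
            batch = gen_structures(cnt, weights, seed=sub_seed + 7919 * ri,
                                   id_prefix=f"{prefix}{ri}") if cnt else []
            structures.extend(batch)
            offset += cnt
        return structures, counts

    sup_structs, sup_counts = build(n_superset, "s", seed)
    held_structs, held_counts = build(n_heldout, "h", seed + 104729)
    superset = label_dataset(sup_structs, oracle)
    heldout = label_dataset(held_structs, oracle)
    manifest = {
        "seed": seed,
        "oracle_seed": oracle.seed,
        "n_superset": n_superset,
        "n_heldout": n_heldout,
        "regime_fractions": fracs,
        "superset_counts": sup_counts,
        "heldout_counts": held_counts,
    }
    return superset, heldout, manifest


def two_regime_benchmark(n_superset: int, n_heldout: int, seed: int = 0,
                         rare_fraction: float = 0.1,
                         oracle: OracleParams | None = None):
    """The canonical heterogeneous fixture: mostly C/N/O molecules with a
    rare fluorine-rich minority, mirroring datasets where unusual
    functional groups drive prediction outliers."""
    return make_benchmark(
        n_superset, n_heldout, oracle=oracle,
        regimes=[(DEFAULT_REGIME, 1.0 - rare_fraction), (FLUORINE_REGIME, rare_fraction)],
        seed=seed,
    )
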