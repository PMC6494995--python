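"""Synthetic dendritic networks, covariates, responses and genotypes.

The generator emulates the sampling design the analysis pipeline expects:
a handful of independent catchments grouped into regions, ~30 riparian
sites of 6–55 diploid individuals genotyped at a dozen microsatellite
loci, genetic diversity accumulating downstream (hydrochory / drift
dynamics), inbreeding linked to a climate-like covariate, and a small
fraction of clonal duplicates.

Networks are random recursive binary trees with log-normal segment
lengths and gamma incremental areas, laid out in the plane so Euclidean
distances are commensurate with in-stream distances.  Site allele
frequencies follow a Dirichlet drift-with-admixture cascade: headwater
sites drift strongly from the basin's ancestral frequencies
(concentration τ_up) while each downstream site re-draws, with milder
drift (τ_down > τ_up), around the drainage-area-weighted mixture of its
upstream sites — so allelic richness accumulates downstream by
construction.  Genotypes are drawn with site-level inbreeding
F_s = expit(base + link·z_s) on a standardised covariate z_s.

Every dataset carries a :class:`SyntheticTruth` record sufficient to
regenerate it bit-for-bit from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariance import CovarianceSpec, mixture_matrix
from .genotypes import MISSING, GenotypeMatrix
from .network import (
    DistanceSet,
    NetworkPoint,
    StreamNetwork,
    build_network,
    hydrologic_index,
    points_from_sites,
)

__all__ = [
    "SyntheticTruth",
    "simulate_network",
    "simulate_sites",
    "simulate_response",
    "simulate_genotypes",
    "study_scale_dataset",
]


@dataclass
class SyntheticTruth:
    """Generating parameters recorded beside every simulated dataset."""

    seed: int
    network: dict = field(default_factory=dict)
    response: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


# ------------------------------------------------------------------ network

def simulate_network(
    n_segments: int = 64,
    n_basins: int = 1,
    seed: int | None = None,
    length_lognorm: tuple[float, float] = (math.log(2000.0), 0.5),
    area_gamma: tuple[float, float] = (2.0, 5.0),
    precip_range: tuple[float, float] = (600.0, 1400.0),
) -> tuple[StreamNetwork, SyntheticTruth]:
    """Random forest of recursive binary stream trees.

    Each basin grows from its outlet by repeatedly attaching two upstream
    children to a random leaf segment.  Lengths (m) are log-normal, the
    incremental contributing areas (km²) gamma, and mean annual
    precipitation follows a smooth gradient from the outlet to the
    headwaters on top of a basin-level base value.
    """
    if n_segments < n_basins:
        raise ValueError("need at least one segment per basin")
    rng = np.random.default_rng(seed)
    per_basin = [n_segments // n_basins] * n_basins
    for i in range(n_segments % n_basins):
        per_basin[i] += 1

    rows = []
    for b, count in enumerate(per_basin, start=1):
        prefix = f"b{b}"
        segs = [f"{prefix}s1"]
        down = {f"{prefix}s1": None}
        leaves = [f"{prefix}s1"]
        nxt = 2
        while len(segs) < count:
            leaf = leaves.pop(int(rng.integers(len(leaves))))
            n_kids = 2 if len(segs) + 2 <= count else 1
            for _ in range(n_kids):
                sid = f"{prefix}s{nxt}"
                nxt += 1
                segs.append(sid)
                down[sid] = leaf
                leaves.append(sid)
        lengths = {s: float(rng.lognormal(*length_lognorm)) for s in segs}
        areas = {s: float(rng.gamma(*area_gamma)) for s in segs}
        # depth of each segment's downstream end for the precip gradient
        depth = {}
        for s in segs:  # segs is in creation order: downstream before upstream
            d = down[s]
            depth[s] = 0.0 if d is None else depth[d] + lengths[d]
        max_depth = max(depth.values()) or 1.0
        base = float(rng.uniform(*precip_range))
        for s in segs:
            precip = base * (1.0 + 0.3 * depth[s] / max_depth) * float(
                rng.uniform(0.95, 1.05)
            )
            rows.append(
                {
                    "segment_id": s,
                    "downstream_id": down[s] if down[s] is not None else "",
                    "length": lengths[s],
                    "area": areas[s],
                    "precip": precip,
                }
            )
    net = build_network(pd.DataFrame(rows))
    truth = SyntheticTruth(
        seed=-1 if seed is None else int(seed),
        network={
            "n_segments": n_segments,
            "n_basins": n_basins,
            "length_lognorm": list(length_lognorm),
            "area_gamma": list(area_gamma),
            "precip_range": list(precip_range),
        },
    )
    return net, truth


def _layout(net: StreamNetwork, rng: np.random.Generator) -> dict[str, tuple]:
    """Planar embedding: (x, y) of each segment's downstream and upstream end.

    Basins sit on a coarse grid 60 km apart; each segment continues its
    parent's bearing with a random turn, so Euclidean distances roughly
    track in-stream distances within a basin.
    """
    coords = {}
    roots = net.roots
    for bi, root in enumerate(roots):
        origin = np.array([60_000.0 * (bi % 3), 60_000.0 * (bi // 3)])
        angle0 = float(rng.uniform(0, 2 * math.pi))
        stack = [(root, origin, angle0)]
        while stack:
            sid, down_xy, angle = stack.pop()
            seg = net.segments[sid]
            up_xy = down_xy + seg.length * np.array([math.cos(angle), math.sin(angle)])
            coords[sid] = (down_xy, up_xy)
            kids = net.children.get(sid, [])
            spread = math.pi / 4
            for j, c in enumerate(kids):
                turn = float(rng.uniform(-spread, spread)) + (j - (len(kids) - 1) / 2) * spread
                stack.append((c, up_xy, angle + turn))
    return coords


def simulate_sites(
    net: StreamNetwork,
    n_sites: int = 30,
    seed: int | None = None,
    level: str = "population",
    distinct_segments: bool = True,
) -> pd.DataFrame:
    """Place sites on distinct random segments with covariates.

    Returns a sites frame (``point_id,segment_id,offset_m,x,y,population,
    basin,ALT,BIOC_TH,BIOC_SO,DA``).  ALT rises with distance upstream;
    the two bioclimatic indices follow smooth planar gradients with noise,
    mimicking thermicity and summer-drought surfaces.
    """
    rng = np.random.default_rng(seed)
    seg_ids = sorted(net.segments)
    if distinct_segments and n_sites > len(seg_ids):
        raise ValueError("more sites than segments")
    # spread sites across basins proportionally to basin size
    chosen = rng.choice(len(seg_ids), size=n_sites, replace=not distinct_segments)
    coords = _layout(net, rng)
    rows = []
    for k, ix in enumerate(sorted(chosen), start=1):
        sid = seg_ids[ix]
        seg = net.segments[sid]
        offset = float(rng.uniform(0, seg.length))
        down_xy, up_xy = coords[sid]
        pos = down_xy + (offset / seg.length) * (up_xy - down_xy)
        dist_up = net.depth[sid] + offset
        alt = 50.0 + 0.05 * dist_up + float(rng.normal(0, 20.0))
        bioc_th = 300.0 - 0.002 * pos[1] + float(rng.normal(0, 15.0))
        bioc_so = 2.0 + 0.00002 * pos[0] + float(rng.normal(0, 0.4))
        point = NetworkPoint(f"site{k}", sid, offset, float(pos[0]), float(pos[1]), level)
        rows.append(
            {
                "point_id": point.point_id,
                "segment_id": sid,
                "offset_m": offset,
                "x": float(pos[0]),
                "y": float(pos[1]),
                "population": point.point_id,
                "basin": net.root_of[sid],
                "ALT": alt,
                "BIOC_TH": bioc_th,
                "BIOC_SO": bioc_so,
                "DA": hydrologic_index(net, point),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- response

def simulate_response(
    dset: DistanceSet,
    spec: CovarianceSpec,
    X: np.ndarray,
    beta: np.ndarray,
    seed: int | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw y = Xβ + L·z with L a factor of the mixture covariance."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError("X and beta disagree")
    S = mixture_matrix(spec, dset)
    w, V = np.linalg.eigh(S)
    if w.min() < -1e-8 * max(np.trace(S), 1.0):
        raise AssertionError("mixture covariance is not PSD")
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal(len(dset))
    y = X @ beta + L @ z
    truth = SyntheticTruth(
        seed=-1 if seed is None else int(seed),
        response={"spec": json.loads(spec.to_json()), "beta": beta.tolist()},
    )
    return y, truth


# ---------------------------------------------------------------- genotypes

def _segment_frequency_cascade(
    net: StreamNetwork,
    ancestral: np.ndarray,
    tau_up: float,
    tau_down: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-segment allele frequencies by drift-with-admixture recursion.

    Headwater (leaf) segments drift strongly from the ancestral
    frequencies (Dirichlet concentration τ_up); every other segment
    re-draws, with milder drift (τ_down), around the PI-weighted mixture
    of its upstream segments' frequencies.  Running the cascade over
    segments rather than sampled sites lets every confluence contribute
    admixture, so allelic evenness accumulates downstream whether or not
    the tributaries are sampled.
    """
    n_loci, K = ancestral.shape
    eps = 1e-6
    freqs: dict[str, np.ndarray] = {}
    order = sorted(net.segments, key=lambda s: net.depth[s], reverse=True)  # leaves first
    for sid in order:
        kids = net.children.get(sid, [])
        out = np.zeros((n_loci, K))
        for l in range(n_loci):
            if not kids:
                out[l] = rng.dirichlet(tau_up * ancestral[l] + eps)
            else:
                mix = sum(net.segments[c].pi * freqs[c][l] for c in kids)
                out[l] = rng.dirichlet(tau_down * np.asarray(mix) + eps)
        freqs[sid] = out
    return freqs


def simulate_genotypes(
    net: StreamNetwork,
    sites: pd.DataFrame,
    K: int = 8,
    n_loci: int = 12,
    n_per_site=None,
    tau_up: float = 20.0,
    tau_down: float = 200.0,
    inbreeding_link: float = 0.0,
    inbreeding_base: float = -6.0,
    link_covariate: str = "BIOC_TH",
    clone_rate: float = 0.01,
    missing_rate: float = 0.01,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Multilocus genotypes with downstream-accumulating diversity.

    Site allele frequencies per locus follow the Dirichlet drift cascade
    described in the module docstring; individuals are drawn with
    site-level inbreeding F_s = expit(inbreeding_base + inbreeding_link·z)
    on the standardised ``link_covariate`` (the default base of −6 keeps
    F ≈ 0 when the link is off, i.e. plain Hardy–Weinberg sampling).
    ``n_per_site`` may be an int, an array, or None for a skewed draw in
    [6, 55] averaging ≈ 20 individuals.  A ``clone_rate`` fraction of
    individuals are vegetative copies of an earlier individual at the same
    site; whole genotypes go missing at ``missing_rate``.
    """
    if K < 2:
        raise ValueError("need at least two ancestral alleles")
    rng = np.random.default_rng(seed)
    points = points_from_sites(sites)
    n_sites = len(points)

    z = sites[link_covariate].to_numpy(dtype=float)
    z = (z - z.mean()) / (z.std() or 1.0)
    F = expit(inbreeding_base + inbreeding_link * z) if np.isfinite(inbreeding_base) else np.zeros(n_sites)

    ancestral = rng.dirichlet(np.ones(K), size=n_loci)
    seg_freqs = _segment_frequency_cascade(net, ancestral, tau_up, tau_down, rng)
    site_freqs = np.stack([seg_freqs[p.segment_id] for p in points])

    if n_per_site is None:
        sizes = np.clip(np.round(rng.gamma(4.0, 5.0, size=n_sites)), 6, 55).astype(int)
    elif np.isscalar(n_per_site):
        sizes = np.full(n_sites, int(n_per_site))
    else:
        sizes = np.asarray(n_per_site, dtype=int)
        if sizes.size != n_sites:
            raise ValueError("n_per_site length must match the number of sites")

    individuals, pops, calls = [], [], []
    clone_pairs = []
    for j in range(n_sites):
        site_calls = []
        for i in range(sizes[j]):
            if i > 0 and rng.random() < clone_rate:
                src = int(rng.integers(i))
                geno = site_calls[src].copy()
                clone_pairs.append((f"{points[j].point_id}_i{src + 1}",
                                    f"{points[j].point_id}_i{i + 1}"))
            else:
                geno = np.zeros((n_loci, 2), dtype=int)
                for l in range(n_loci):
                    p = site_freqs[j, l]
                    if rng.random() < F[j]:
                        a = int(rng.choice(K, p=p))
                        geno[l] = (a + 1, a + 1)
                    else:
                        a, b = rng.choice(K, size=2, p=p)
                        geno[l] = tuple(sorted((int(a) + 1, int(b) + 1)))
            site_calls.append(geno)
            individuals.append(f"{points[j].point_id}_i{i + 1}")
            pops.append(points[j].point_id)
        calls.extend(site_calls)
    calls = np.array(calls, dtype=int)
    if missing_rate > 0:
        drop = rng.random(calls.shape[:2]) < missing_rate
        calls[drop] = MISSING

    G = GenotypeMatrix(individuals, pops, [f"L{l + 1:02d}" for l in range(n_loci)], calls)
    truth = SyntheticTruth(
        seed=-1 if seed is None else int(seed),
        genotypes={
            "K": K,
            "n_loci": n_loci,
            "sizes": sizes.tolist(),
            "tau_up": tau_up,
            "tau_down": tau_down,
            "inbreeding_link": inbreeding_link,
            "inbreeding_base": inbreeding_base,
            "link_covariate": link_covariate,
            "clone_rate": clone_rate,
            "missing_rate": missing_rate,
            "clone_pairs": clone_pairs,
            "site_F": F.tolist(),
        },
    )
    return G, truth


# ------------------------------------------------------------------ preset

def study_scale_dataset(seed: int = 0, n_segments: int = 200, n_sites: int = 30):
    """A study-scale fixture: 8 basins in 3 regions, 30 sites, 12 loci.

    Returns ``(net, sites, genotypes, truth)``.  Two regions are single
    basins and the third groups the remaining six; sampling sizes average
    ~20 individuals per site, giving on the order of 600 trees in total.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_sites, s_geno = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    net, t_net = simulate_network(n_segments=n_segments, n_basins=8, seed=s_net)
    sites = simulate_sites(net, n_sites=n_sites, seed=s_sites)
    region_map = {}
    for bi, root in enumerate(net.roots):
        region_map[root] = ["TUA", "ZEZ"][bi] if bi < 2 else "ALG"
    sites = sites.assign(region=[region_map[b] for b in sites["basin"]])
    G, t_gen = simulate_genotypes(
        net, sites, K=8, n_loci=12, tau_up=20.0, tau_down=200.0,
        inbreeding_link=1.0, clone_rate=0.01, missing_rate=0.01, seed=s_geno,
    )
    truth = SyntheticTruth(seed=seed, network=t_net.network, genotypes=t_gen.genotypes)
    return net, sites, G, truth
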