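"""Codominant genotypes and microsatellite diversity/differentiation estimators.

Genotypes are diploid unordered allele pairs (positive integer codes) at a
set of loci; a missing genotype is whole (both alleles absent, coded 0 on
file).  Per-population estimators:

* Ho — observed heterozygosity (heterozygote fraction among scored);
* He — expected heterozygosity 1 − Σp²;
* uHe — unbiased expected heterozygosity, 2n/(2n−1)·He with n the
  individuals scored at the locus;
* Ae — effective number of alleles, 1/Σp²;
* AR — mean number of alleles; PA — mean private alleles per locus;
* Fis — multilocus inbreeding coefficient 1 − mean(Ho)/mean(uHe), negative
  under heterozygote excess;
* HL — per-individual homozygosity level: the expected-heterozygosity-
  weighted share of the individual's scored loci that are homozygous.

Hardy–Weinberg departures are tested by permutation (re-pairing alleles
within population × locus), with one-sided p-values for heterozygote
excess (P1) and deficit (P2).  Differentiation reports Weir–Cockerham θ,
Gst, Hedrick's G'st and Jost's D.  Multiple testing uses the
Benjamini–Yekutieli step-up correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "diversity_per_population",
    "individual_hl",
    "hwe_tests",
    "differentiation",
    "by_correction",
    "find_clones",
]

MISSING = 0


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid codominant calls with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2); allele code 0 marks a
    missing (whole) genotype.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(self.populations) != n:
            raise ValueError("every individual needs a population label")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-called genotypes are not allowed (missing is whole)")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be positive (0 = missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_order(self) -> list[str]:
        return list(dict.fromkeys(self.populations))

    def scored(self) -> np.ndarray:
        """Boolean (n, L): genotype present."""
        return self.calls[:, :, 0] != MISSING

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.populations])

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, (ind, pop) in enumerate(zip(self.individuals, self.populations)):
            for l, locus in enumerate(self.loci):
                a1, a2 = self.calls[i, l]
                rows.append((ind, pop, locus, int(a1), int(a2)))
        return pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"])


# ---------------------------------------------------------------------- I/O

def read_genotypes(path, dialect: str = "long") -> GenotypeMatrix:
    """Read genotypes from a long CSV or a GenAlEx-style wide CSV.

    long: columns ``individual,population,locus,allele1,allele2``;
    genalex: three header rows (counts; title and population names; column
    names with two columns per locus), then one row per individual of
    ``sample, population, a1, a2, a1, a2, ...``.  0 codes become missing.
    """
    if dialect == "long":
        tab = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
        required = ["individual", "population", "locus", "allele1", "allele2"]
        missing = [c for c in required if c not in tab.columns]
        if missing:
            raise ValueError(f"long genotype file missing columns: {missing}")
        loci = list(dict.fromkeys(tab["locus"]))
        inds, pops = [], {}
        for ind, pop in zip(tab["individual"], tab["population"]):
            if ind not in pops:
                inds.append(ind)
                pops[ind] = pop
            elif pops[ind] != pop:
                raise ValueError(f"individual {ind!r} listed in two populations")
        calls = np.zeros((len(inds), len(loci), 2), dtype=int)
        ind_ix = {v: i for i, v in enumerate(inds)}
        loc_ix = {v: i for i, v in enumerate(loci)}
        for _, r in tab.iterrows():
            a1, a2 = int(r["allele1"]), int(r["allele2"])
            if (a1 == MISSING) != (a2 == MISSING):
                raise ValueError(f"half-called genotype for {r['individual']!r}/{r['locus']!r}")
            calls[ind_ix[r["individual"]], loc_ix[r["locus"]]] = (a1, a2)
        return GenotypeMatrix(inds, [pops[i] for i in inds], loci, calls)

    if dialect == "genalex":
        raw = pd.read_csv(path, header=None, skiprows=2, dtype=str).fillna("")
        header = list(raw.iloc[0])
        loci = [h for h in header[2:] if h != ""]
        body = raw.iloc[1:]
        n_allele_cols = len(header) - 2
        if n_allele_cols != 2 * len(loci):
            raise ValueError("genalex layout needs two columns per locus")
        inds = [str(v) for v in body.iloc[:, 0]]
        pops = [str(v) for v in body.iloc[:, 1]]
        alleles = body.iloc[:, 2:].replace("", "0").astype(int).to_numpy()
        calls = alleles.reshape(len(inds), len(loci), 2)
        bad = (calls == MISSING).sum(axis=2) == 1
        calls[bad] = MISSING
        return GenotypeMatrix(inds, pops, loci, calls)

    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "long") -> None:
    if dialect == "long":
        G.to_long().to_csv(path, index=False)
        return
    if dialect == "genalex":
        pops = G.population_order
        sizes = [sum(p == q for q in G.populations) for p in pops]
        lines = [
            ",".join(map(str, [G.n_loci, G.n_individuals, len(pops), *sizes])),
            ",".join(["dataset", "", *pops] + [""] * max(0, 2 * G.n_loci - len(pops))),
            ",".join(["sample", "population"] + [x for l in G.loci for x in (l, "")]),
        ]
        for i, (ind, pop) in enumerate(zip(G.individuals, G.populations)):
            row = [ind, pop] + [str(int(a)) for a in G.calls[i].ravel()]
            lines.append(",".join(row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# -------------------------------------------------------- allele frequencies

def allele_frequencies(G: GenotypeMatrix, by: str = "population"):
    """Per-locus allele frequency tables.

    Returns ``{group: {locus: pandas.Series allele -> frequency}}``; with
    ``by='all'`` the single group is ``'all'``.  Empty locus × group cells
    yield an empty Series.
    """
    if by == "population":
        groups = {p: G.pop_mask(p) for p in G.population_order}
    elif by == "all":
        groups = {"all": np.ones(G.n_individuals, dtype=bool)}
    else:
        raise ValueError("by must be 'population' or 'all'")
    out: dict[str, dict[str, pd.Series]] = {}
    for g, mask in groups.items():
        out[g] = {}
        for l, locus in enumerate(G.loci):
            alleles = G.calls[mask, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            if alleles.size == 0:
                out[g][locus] = pd.Series(dtype=float)
            else:
                counts = pd.Series(alleles).value_counts().sort_index()
                out[g][locus] = counts / counts.sum()
    return out


def _locus_stats(G: GenotypeMatrix, mask: np.ndarray):
    """Per-locus (n, Ho, He, uHe, Ae, AR) for the individuals in ``mask``."""
    stats = []
    for l in range(G.n_loci):
        calls = G.calls[mask, l, :]
        scored = calls[:, 0] != MISSING
        n = int(scored.sum())
        if n == 0:
            stats.append((0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        cs = calls[scored]
        ho = float((cs[:, 0] != cs[:, 1]).mean())
        _, counts = np.unique(cs.ravel(), return_counts=True)
        p = counts / counts.sum()
        sp2 = float((p**2).sum())
        he = 1.0 - sp2
        uhe = 2 * n / (2 * n - 1) * he if n > 1 else he
        stats.append((n, ho, he, uhe, 1.0 / sp2, float(len(p))))
    return pd.DataFrame(stats, columns=["n", "Ho", "He", "uHe", "Ae", "AR"], index=G.loci)


def _private_alleles(G: GenotypeMatrix) -> dict[str, float]:
    """Mean number per locus of alleles found in one population only."""
    freqs = allele_frequencies(G, by="population")
    pops = G.population_order
    pa = {p: 0 for p in pops}
    for l, locus in enumerate(G.loci):
        present = {p: set(freqs[p][locus].index) for p in pops}
        for p in pops:
            others = set().union(*(present[q] for q in pops if q != p)) if len(pops) > 1 else set()
            pa[p] += len(present[p] - others)
    return {p: pa[p] / G.n_loci for p in pops}


def diversity_per_population(G: GenotypeMatrix) -> pd.DataFrame:
    """Population diversity table: n, Ae, AR, uHe, Ho, He, Fis, PA.

    Population values are unweighted means over loci with data; Fis is the
    multilocus 1 − mean(Ho)/mean(uHe) (0 when mean uHe is 0).
    """
    pa = _private_alleles(G)
    rows = []
    for pop in G.population_order:
        mask = G.pop_mask(pop)
        st = _locus_stats(G, mask)
        ok = st["n"] > 0
        if not ok.any():
            raise ValueError(f"population {pop!r} has no scored genotypes at any locus")
        mean_ho = float(st.loc[ok, "Ho"].mean())
        mean_uhe = float(st.loc[ok, "uHe"].mean())
        fis = 1.0 - mean_ho / mean_uhe if mean_uhe > 0 else 0.0
        rows.append(
            {
                "population": pop,
                "n": int(mask.sum()),
                "Ae": float(st.loc[ok, "Ae"].mean()),
                "AR": float(st.loc[ok, "AR"].mean()),
                "uHe": mean_uhe,
                "Ho": mean_ho,
                "He": float(st.loc[ok, "He"].mean()),
                "Fis": fis,
                "PA": pa[pop],
            }
        )
    return pd.DataFrame(rows).set_index("population")


def individual_hl(G: GenotypeMatrix) -> pd.Series:
    """Homozygosity level per individual, in [0, 1].

    HL = ΣE_hom / (ΣE_hom + ΣE_het), with E the locus expected
    heterozygosity in the individual's population; weighting homozygosity
    by locus information content makes HL comparable across individuals
    typed at different loci.  Individuals with no scored locus get NaN.
    """
    he_by_pop = {p: _locus_stats(G, G.pop_mask(p))["He"].to_numpy() for p in G.population_order}
    out = []
    for i, pop in enumerate(G.populations):
        calls = G.calls[i]
        scored = calls[:, 0] != MISSING
        if not scored.any():
            out.append(np.nan)
            continue
        E = he_by_pop[pop]
        hom = scored & (calls[:, 0] == calls[:, 1])
        het = scored & (calls[:, 0] != calls[:, 1])
        num = float(np.nansum(E[hom]))
        den = num + float(np.nansum(E[het]))
        out.append(num / den if den > 0 else np.nan)
    return pd.Series(out, index=G.individuals, name="HL")


# ----------------------------------------------------------------- HWE test

def _multilocus_fis(ho_means: np.ndarray, uhe_mean: float) -> float:
    return 1.0 - float(ho_means.mean()) / uhe_mean if uhe_mean > 0 else 0.0


def hwe_tests(G: GenotypeMatrix, n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Permutation Hardy–Weinberg test per population.

    The statistic is the multilocus Fis; the null re-pairs the observed
    alleles into diploid genotypes within each population × locus.  P1
    tests heterozygote excess (permuted Fis ≤ observed) and P2 deficit
    (permuted Fis ≥ observed); both use the add-one Monte-Carlo estimator.
    Populations with fewer than two scored individuals get NaN p-values.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    rows = []
    for pop in G.population_order:
        mask = G.pop_mask(pop)
        st = _locus_stats(G, mask)
        ok = (st["n"] > 1) & (st["uHe"] > 0)
        if not ok.any():
            rows.append({"population": pop, "Fis": np.nan, "P1": np.nan, "P2": np.nan})
            continue
        uhe_mean = float(st.loc[ok, "uHe"].mean())
        obs = _multilocus_fis(st.loc[ok, "Ho"].to_numpy(), uhe_mean)
        # permuted Ho per locus: shuffle the pooled alleles and re-pair
        perm_ho = np.zeros((n_perm, int(ok.sum())))
        for k, locus in enumerate(st.index[ok]):
            l = G.loci.index(locus)
            calls = G.calls[mask, l, :]
            scored = calls[:, 0] != MISSING
            alleles = calls[scored].ravel()
            tiled = np.tile(alleles, (n_perm, 1))
            shuffled = rng.permuted(tiled, axis=1).reshape(n_perm, -1, 2)
            perm_ho[:, k] = (shuffled[:, :, 0] != shuffled[:, :, 1]).mean(axis=1)
        perm_fis = 1.0 - perm_ho.mean(axis=1) / uhe_mean
        p1 = (1 + int((perm_fis <= obs + 1e-12).sum())) / (n_perm + 1)
        p2 = (1 + int((perm_fis >= obs - 1e-12).sum())) / (n_perm + 1)
        rows.append({"population": pop, "Fis": obs, "P1": p1, "P2": p2})
    return pd.DataFrame(rows).set_index("population")


# --------------------------------------------------------- differentiation

def _theta_wc(G: GenotypeMatrix, pops: list[str]) -> float:
    """Weir–Cockerham θ, ratio of summed a over a+b+c across loci/alleles."""
    num = den = 0.0
    for l in range(G.n_loci):
        datasets = []
        for pop in pops:
            calls = G.calls[G.pop_mask(pop), l, :]
            scored = calls[:, 0] != MISSING
            if scored.sum() > 0:
                datasets.append(calls[scored])
        r = len(datasets)
        if r < 2:
            continue
        ni = np.array([len(d) for d in datasets], dtype=float)
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
        alleles = np.unique(np.concatenate([d.ravel() for d in datasets]))
        for al in alleles:
            pi = np.array([(d == al).sum() / (2 * len(d)) for d in datasets])
            hi = np.array([((d[:, 0] == al) ^ (d[:, 1] == al)).mean() for d in datasets])
            pbar = (ni * pi).sum() / (r * nbar)
            s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ni * hi).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den if den != 0 else np.nan


def differentiation(G: GenotypeMatrix, grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Fixation and allelic differentiation per group of populations.

    ``grouping`` maps population -> group (region); None analyses all
    populations as one group ('all').  Reports k (populations), Fst
    (Weir–Cockerham θ), Gst = (Ht−Hs)/Ht, Hedrick's
    G'st = Gst·(k−1+Hs)/((k−1)(1−Hs)), and Jost's
    D = (k/(k−1))·(Ht−Hs)/(1−Hs), where Hs is the unweighted mean
    within-population He and Ht the He of the unweighted mean allele
    frequencies, each averaged over polymorphic-capable loci.
    """
    if grouping is None:
        grouping = {p: "all" for p in G.population_order}
    groups: dict[str, list[str]] = {}
    for pop in G.population_order:
        g = grouping.get(pop)
        if g is not None:
            groups.setdefault(g, []).append(pop)
    freqs = allele_frequencies(G, by="population")
    rows = []
    for g, pops in groups.items():
        if len(pops) < 2:
            raise ValueError(f"group {g!r} needs at least two populations")
        hs_l, ht_l, k_l = [], [], []
        for locus in G.loci:
            tabs = [freqs[p][locus] for p in pops if len(freqs[p][locus]) > 0]
            k = len(tabs)
            if k < 2:
                continue
            hs = np.mean([1.0 - float((t**2).sum()) for t in tabs])
            mean_p = pd.concat(tabs, axis=1).fillna(0.0).mean(axis=1)
            ht = 1.0 - float((mean_p**2).sum())
            hs_l.append(hs)
            ht_l.append(ht)
            k_l.append(k)
        if not ht_l:
            rows.append({"group": g, "k": len(pops), "Fst": np.nan, "Gst": np.nan,
                         "Gpst": np.nan, "D_Jost": np.nan})
            continue
        hs, ht = float(np.mean(hs_l)), float(np.mean(ht_l))
        k = float(np.mean(k_l))
        if ht <= 0:
            gst = gpst = d = np.nan
        else:
            gst = (ht - hs) / ht
            gpst = gst * (k - 1 + hs) / ((k - 1) * (1 - hs)) if hs < 1 else np.nan
            d = (k / (k - 1)) * (ht - hs) / (1 - hs) if hs < 1 else np.nan
        rows.append(
            {"group": g, "k": len(pops), "Fst": _theta_wc(G, pops),
             "Gst": gst, "Gpst": gpst, "D_Jost": d}
        )
    return pd.DataFrame(rows).set_index("group")


# ------------------------------------------------------------ B-Y correction

def by_correction(pvalues, alpha: float = 0.05):
    """Benjamini–Yekutieli step-up FDR control under arbitrary dependence.

    Returns ``(reject, threshold)`` where ``reject`` is a boolean array in
    the original order and ``threshold`` is the largest step-up cutoff
    ``k*·alpha/(m·c(m))`` (0 when nothing is rejected), with
    ``c(m) = Σ_{i=1..m} 1/i``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    cm = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    cuts = ranks * alpha / (m * cm)
    passed = np.nonzero(p[order] <= cuts)[0]
    reject = np.zeros(m, dtype=bool)
    if passed.size == 0:
        return reject, 0.0
    kstar = passed[-1]
    reject[order[: kstar + 1]] = True
    return reject, float(cuts[kstar])


# ------------------------------------------------------------------- clones

def find_clones(G: GenotypeMatrix) -> pd.DataFrame:
    """Group identical multilocus genotypes and score their sexual origin.

    Two individuals are clonemates only if every locus matches exactly,
    missing pattern included.  For each repeated genotype the probability
    of drawing it once under random mating (p_gen, whole-dataset allele
    frequencies) and the probability that at least one of the other N−1
    individuals shares it by independent sexual reproduction
    (Psex = 1 − (1 − p_gen)^(N−1)) are reported.  Empty frame when all
    genotypes are unique.
    """
    keys: dict[tuple, list[int]] = {}
    for i in range(G.n_individuals):
        key = tuple(map(tuple, np.sort(G.calls[i], axis=1)))
        keys.setdefault(key, []).append(i)
    freqs = allele_frequencies(G, by="all")["all"]
    N = G.n_individuals
    rows = []
    for gid, (key, members) in enumerate(sorted(keys.items(), key=lambda kv: kv[1][0])):
        if len(members) < 2:
            continue
        p_gen = 1.0
        for l, locus in enumerate(G.loci):
            a1, a2 = key[l]
            if a1 == MISSING:
                continue
            f = freqs[locus]
            if a1 == a2:
                p_gen *= float(f.get(a1, 0.0)) ** 2
            else:
                p_gen *= 2.0 * float(f.get(a1, 0.0)) * float(f.get(a2, 0.0))
        psex = 1.0 - (1.0 - p_gen) ** (N - 1)
        rows.append(
            {
                "group": gid,
                "members": ",".join(G.individuals[i] for i in members),
                "size": len(members),
                "p_gen": p_gen,
                "Psex": psex,
            }
        )
    return pd.DataFrame(rows, columns=["group", "members", "size", "p_gen", "Psex"])
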