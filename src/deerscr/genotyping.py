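"""Consensus genotyping, individual matching and marker summaries.

Fecal-DNA microsatellite genotypes are noisy: amplification can fail outright
and heterozygotes can drop one allele.  The multitubes protocol runs several
PCR replicates per sample and accepts a locus call only when alleles are
confirmed often enough — here, a heterozygote needs each allele seen in at
least two replicates, a homozygote needs its allele in at least three.
Samples with enough called loci are then matched into individuals under a
mismatch-tolerant rule, and per-locus summaries (probability of identity,
heterozygosities) quantify how informative the marker panel is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAIL",
    "NOCALL",
    "ReplicateCalls",
    "ConsensusGenotype",
    "IndividualAssignment",
    "consensus_call",
    "build_consensus",
    "quality_filter",
    "pairwise_match",
    "cluster_individuals",
    "allele_frequencies",
    "pi_locus",
    "pisib_locus",
    "pi_statistics",
    "heterozygosity",
    "read_replicate_calls",
]

#: Sentinel for a failed PCR replicate.
FAIL = None
#: Sentinel for a locus without an accepted consensus call.
NOCALL = None

Allele = str
Pair = tuple[Allele, Allele]


def _norm_pair(pair) -> Pair:
    a, b = pair
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class ReplicateCalls:
    """Raw per-sample PCR replicate calls.

    ``calls`` maps locus name -> list of replicate results, each an unordered
    allele pair or :data:`FAIL`.
    """

    sample: str
    calls: dict[str, list[Pair | None]]
    session: str | None = None
    trap: str | None = None
    occasion: int | None = None


@dataclass
class ConsensusGenotype:
    """Accepted multilocus genotype of one sample (NOCALL loci omitted from
    ``n_called``)."""

    sample: str
    loci: dict[str, Pair | None]
    session: str | None = None
    trap: str | None = None
    occasion: int | None = None

    @property
    def n_called(self) -> int:
        return sum(1 for g in self.loci.values() if g is not None)


@dataclass
class IndividualAssignment:
    """Sample -> individual mapping with per-individual sex."""

    sample_to_individual: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)  # individual -> F/M/unknown
    flagged: set[str] = field(default_factory=set)  # non-transitive components

    @property
    def individuals(self) -> list[str]:
        seen: list[str] = []
        for ind in self.sample_to_individual.values():
            if ind not in seen:
                seen.append(ind)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "individual": i,
                "sex": self.sex.get(i, "unknown"),
                "flagged": i in self.flagged,
            }
            for s, i in self.sample_to_individual.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus calling

def consensus_call(replicates: list[Pair | None]) -> Pair | None:
    """Accept a locus call from PCR replicates under the multitubes rule.

    A replicate showing alleles (A, B) counts one amplification for each of A
    and B.  Heterozygote (A, B) is accepted iff both alleles appear in >= 2
    replicates; homozygote (A, A) iff A appears in >= 3 replicates and no
    second allele is confirmed.  When two distinct alleles each reach the
    homozygote threshold but the heterozygote was never itself confirmed
    twice, the locus stays NOCALL (conservative).  Otherwise NOCALL.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    counts: dict[Allele, int] = {}
    pair_counts: dict[Pair, int] = {}
    for rep in replicates:
        if rep is None:
            continue
        a, b = _norm_pair(rep)
        counts[a] = counts.get(a, 0) + 1
        if b != a:
            counts[b] = counts.get(b, 0) + 1
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    confirmed2 = sorted(a for a, c in counts.items() if c >= 2)
    if len(confirmed2) >= 2:
        if len(confirmed2) > 2:
            return NOCALL  # three alleles confirmed: contamination-like, reject
        a, b = confirmed2
        # two alleles each at the homozygote threshold that were never seen
        # together twice look like two co-sampled homozygotes, not a het
        if counts[a] >= 3 and counts[b] >= 3 and pair_counts.get((a, b), 0) < 2:
            return NOCALL
        return (a, b)
    if len(confirmed2) == 1:
        a = confirmed2[0]
        if counts[a] >= 3:
            return (a, a)
    return NOCALL


def build_consensus(rep: ReplicateCalls) -> ConsensusGenotype:
    loci = {locus: consensus_call(reps) for locus, reps in rep.calls.items()}
    return ConsensusGenotype(
        sample=rep.sample, loci=loci,
        session=rep.session, trap=rep.trap, occasion=rep.occasion,
    )


def quality_filter(genotype: ConsensusGenotype, min_loci: int = 11) -> bool:
    """Keep a sample only if enough loci were called to identify individuals."""
    if min_loci > len(genotype.loci):
        raise ValueError("min_loci exceeds the panel size")
    return genotype.n_called >= min_loci


def pairwise_match(g1: ConsensusGenotype, g2: ConsensusGenotype,
                   max_mismatch: int = 2, min_match: int = 6) -> bool:
    """Same-individual decision over loci called in *both* samples.

    Loci called in only one sample are ignored (neither match nor mismatch).
    """
    n_eq = n_neq = 0
    for locus, a in g1.loci.items():
        b = g2.loci.get(locus)
        if a is None or b is None:
            continue
        if _norm_pair(a) == _norm_pair(b):
            n_eq += 1
        else:
            n_neq += 1
    return n_neq <= max_mismatch and n_eq >= min_match


def cluster_individuals(genotypes: list[ConsensusGenotype],
                        sample_sex: dict[str, str] | None = None,
                        max_mismatch: int = 2, min_match: int = 6,
                        id_prefix: str = "ind") -> IndividualAssignment:
    """Single-linkage clustering of the pairwise-match graph.

    Components containing at least one non-matching pair (the match relation
    is not transitive) are flagged.  Individual ids are assigned in
    first-seen sample order, so the numbering is deterministic.  Sex attaches
    to individuals; conflicting sexed samples inside one individual flag it
    and set sex to ``unknown``.
    """
    n = len(genotypes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    match = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        if pairwise_match(genotypes[i], genotypes[j], max_mismatch, min_match):
            match[i, j] = match[j, i] = True
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    comp_ids: dict[int, str] = {}
    mapping: dict[str, str] = {}
    members: dict[str, list[int]] = {}
    k = 0
    for i in range(n):
        root = find(i)
        if root not in comp_ids:
            k += 1
            comp_ids[root] = f"{id_prefix}{k:03d}"
        ind = comp_ids[root]
        mapping[genotypes[i].sample] = ind
        members.setdefault(ind, []).append(i)

    flagged: set[str] = set()
    for ind, idx in members.items():
        for i, j in itertools.combinations(idx, 2):
            if not match[i, j]:
                flagged.add(ind)
                break

    sex: dict[str, str] = {}
    if sample_sex:
        for ind, idx in members.items():
            sexes = {
                sample_sex[genotypes[i].sample]
                for i in idx
                if sample_sex.get(genotypes[i].sample) in ("F", "M")
            }
            if len(sexes) == 1:
                sex[ind] = sexes.pop()
            elif len(sexes) > 1:
                sex[ind] = "unknown"
                flagged.add(ind)
            else:
                sex[ind] = "unknown"
    return IndividualAssignment(mapping, sex, flagged)


# ---------------------------------------------------------------------------
# Marker summaries

def allele_frequencies(genotypes: list[ConsensusGenotype]) -> dict[str, dict[Allele, float]]:
    """Relative allele frequencies per locus from called genotypes."""
    counts: dict[str, dict[Allele, int]] = {}
    for g in genotypes:
        for locus, pair in g.loci.items():
            if pair is None:
                continue
            a, b = _norm_pair(pair)
            d = counts.setdefault(locus, {})
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
    freqs: dict[str, dict[Allele, float]] = {}
    for locus, d in counts.items():
        tot = sum(d.values())
        freqs[locus] = {a: c / tot for a, c in d.items()}
    return freqs


def pi_locus(p: np.ndarray) -> float:
    """Probability that two random individuals share this locus genotype
    under Hardy-Weinberg: ``2 (sum p^2)^2 - sum p^4``."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 2 * s2 ** 2 - s4


def pisib_locus(p: np.ndarray) -> float:
    """Probability of identity among full siblings at one locus:
    ``0.25 + 0.5 sum p^2 + 0.5 (sum p^2)^2 - 0.25 sum p^4``."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def pi_statistics(freqs: dict[str, dict[Allele, float]],
                  k_worst: int = 6) -> tuple[float, float]:
    """Multilocus PI and PIsib over the ``k_worst`` *least informative* loci
    (those with the largest per-locus values)."""
    if k_worst > len(freqs):
        raise ValueError("k_worst exceeds the number of loci")
    pis = sorted((pi_locus(np.array(list(p.values()))) for p in freqs.values()),
                 reverse=True)
    pisibs = sorted((pisib_locus(np.array(list(p.values()))) for p in freqs.values()),
                    reverse=True)
    return float(np.prod(pis[:k_worst])), float(np.prod(pisibs[:k_worst]))


def heterozygosity(freqs: dict[str, dict[Allele, float]],
                   genotypes: list[ConsensusGenotype]) -> pd.DataFrame:
    """Expected (1 - sum p^2) and observed (fraction heterozygous among
    called genotypes) heterozygosity and allele count per locus."""
    rows = []
    for locus, p in freqs.items():
        pv = np.array(list(p.values()))
        he = 1.0 - float(np.sum(pv ** 2))
        called = [g.loci[locus] for g in genotypes
                  if locus in g.loci and g.loci[locus] is not None]
        if not called:
            raise ValueError(f"no called genotypes at locus {locus}")
        ho = float(np.mean([a != b for a, b in called]))
        rows.append({"locus": locus, "n_alleles": len(p), "He": he, "Ho": ho})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O — long-format delimited text: sample,locus,replicate,allele1,allele2
# (FAIL encoded as empty allele fields)

def read_replicate_calls(path, meta: pd.DataFrame | None = None) -> list[ReplicateCalls]:
    """Read long-format replicate calls.

    ``meta`` optionally maps sample -> session/trap/occasion (columns named
    exactly so, indexed or with a ``sample`` column).
    """
    df = pd.read_csv(path, dtype={"sample": str, "locus": str}, keep_default_na=False)
    if meta is not None and "sample" in meta.columns:
        meta = meta.set_index("sample")
    out: list[ReplicateCalls] = []
    for sample, grp in df.groupby("sample", sort=False):
        calls: dict[str, list[Pair | None]] = {}
        for locus, lgrp in grp.groupby("locus", sort=False):
            reps: list[Pair | None] = []
            for _, row in lgrp.sort_values("replicate").iterrows():
                a1, a2 = str(row["allele1"]).strip(), str(row["allele2"]).strip()
                reps.append(None if a1 == "" or a2 == "" else _norm_pair((a1, a2)))
            calls[locus] = reps
        kw = {}
        if meta is not None and sample in meta.index:
            row = meta.loc[sample]
            kw = {
                "session": str(row.get("session")) if "session" in meta.columns else None,
                "trap": str(row.get("trap")) if "trap" in meta.columns else None,
                "occasion": int(row.get("occasion")) if "occasion" in meta.columns else None,
            }
        out.append(ReplicateCalls(sample=str(sample), calls=calls, **kw))
    return out


def write_replicate_calls(reps: list[ReplicateCalls], path) -> None:
    rows = []
    for r in reps:
        for locus, lst in r.calls.items():
            for k, pair in enumerate(lst, start=1):
                a1, a2 = ("", "") if pair is None else pair
                rows.append({"sample": r.sample, "locus": locus, "replicate": k,
                             "allele1": a1, "allele2": a2})
    pd.DataFrame(rows).to_csv(path, index=False)
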