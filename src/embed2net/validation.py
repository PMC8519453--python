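"""Embedding validation against knowledgebase structure.

Compares cosine similarities of entity pairs that share curated structure
(pathway membership, disease-ontology groups, protein-protein interactions,
drug target overlap) with randomly sampled pairs. Within-group similarity is
summarized by quartiles per group, and the trend of the median against group
size is captured by the decay curve f(x) = (x^a + b)^-1 or by a Loess
smoother.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .embedding import Embedding
from .errors import FitError, ParameterError, SamplingError

Pair = tuple[str, str]


def _canon(pair: Iterable[str]) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class EntityGroup:
    group_id: str
    entity_type: str
    members: frozenset[str]

    def present_members(self, embedding: Embedding) -> list[str]:
        return sorted(m for m in self.members if m in embedding)


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    size: int          # members present in the embedding
    q1: float
    median: float
    q3: float


@dataclass(frozen=True)
class DecayFit:
    a: float
    b: float
    rss: float
    converged: bool
    init: tuple[float, float]

    def __call__(self, x):
        return 1.0 / (np.asarray(x, dtype=float) ** self.a + self.b)


@dataclass
class PairedSimilaritySample:
    positive_pairs: list[Pair]
    positive_cosines: np.ndarray
    random_pairs: list[Pair]
    random_cosines: np.ndarray
    requested_n: int

    def quartiles(self) -> pd.DataFrame:
        rows = {}
        for arm, values in (("positive", self.positive_cosines),
                            ("random", self.random_cosines)):
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows[arm] = {"q1": q1, "median": med, "q3": q3, "n": len(values)}
        return pd.DataFrame(rows).T


@dataclass
class DrugTargetTable:
    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugTargetTable":
        acc: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                drug, _, gene = line.partition("\t")
                acc.setdefault(drug, set()).add(gene)
        return cls({d: frozenset(g) for d, g in acc.items()})

    def shared(self, drug_a: str, drug_b: str) -> int:
        return len(self.targets.get(drug_a, frozenset())
                   & self.targets.get(drug_b, frozenset()))


# -- file readers ----------------------------------------------------------

def read_gmt(path: str | Path, entity_type: str = "gene") -> list[EntityGroup]:
    """GMT format: group_id <TAB> description <TAB> member..."""
    groups = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            groups.append(EntityGroup(parts[0], entity_type,
                                      frozenset(parts[2:])))
    return groups


def read_pair_tsv(path: str | Path) -> list[Pair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, _, b = line.partition("\t")
            pairs.append(_canon((a, b)))
    return pairs


# -- operations ------------------------------------------------------------

def pairwise_cosine_values(embedding: Embedding,
                           terms: Sequence[str]) -> np.ndarray:
    """All x*(x-1)/2 pairwise cosines of the given in-vocabulary terms."""
    sims = embedding.pairwise_cosines(terms)
    iu = np.triu_indices(len(terms), k=1)
    return sims[iu]


def group_similarity_summary(embedding: Embedding,
                             groups: Sequence[EntityGroup],
                             min_size: int = 10,
                             max_size: int = 3000) -> list[GroupSummary]:
    """Quartiles of within-group pairwise cosines, filtered by group size.

    The size filter applies to the members present in the embedding.
    Quartiles use numpy's linear-interpolation convention.
    """
    if min_size < 2:
        raise ParameterError("min_size must be >= 2")
    out = []
    for group in groups:
        present = group.present_members(embedding)
        x = len(present)
        if x < min_size or x > max_size:
            continue
        values = pairwise_cosine_values(embedding, present)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        out.append(GroupSummary(group.group_id, x, float(q1), float(med),
                                float(q3)))
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.group_id, s.size, s.q1, s.median, s.q3) for s in summaries],
        columns=["group_id", "x", "q1", "median", "q3"])


def sample_random_pairs(terms: Sequence[str], n: int,
                        excluded_pairs: Iterable[Pair] = (),
                        seed: int = 0) -> list[Pair]:
    """n distinct unordered pairs drawn uniformly without replacement."""
    if n == 0:
        return []
    terms = sorted(set(terms))
    excluded = {_canon(p) for p in excluded_pairs}
    m = len(terms)
    universe = m * (m - 1) // 2
    admissible = universe - sum(
        1 for p in excluded if p[0] in terms and p[1] in terms and p[0] != p[1])
    if admissible < n:
        raise SamplingError(
            f"requested {n} pairs but only {admissible} admissible "
            f"(deficit {n - admissible})")
    rng = np.random.default_rng(seed)
    if universe <= 500_000:
        all_pairs = [p for p in itertools.combinations(terms, 2)
                     if p not in excluded]
        idx = rng.choice(len(all_pairs), size=n, replace=False)
        return [all_pairs[i] for i in sorted(idx)]
    chosen: set[Pair] = set()
    while len(chosen) < n:
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        p = _canon((terms[i], terms[j]))
        if p not in excluded:
            chosen.add(p)
    return sorted(chosen)


def _decay(x, a, b):
    return 1.0 / (np.power(x, a) + b)


def fit_decay(summaries: Sequence[GroupSummary]) -> DecayFit:
    """Least-squares fit of f(x) = (x^a + b)^-1 to group medians.

    Initialized at (a, b) = (1, 0) with bound a > 0; on failure, multi-start
    from a in {0.1, 0.5, 1, 2}.
    """
    xs = np.array([s.size for s in summaries], dtype=float)
    ys = np.array([s.median for s in summaries], dtype=float)
    if len(np.unique(xs)) < 3:
        raise ParameterError("need >= 3 summaries with distinct sizes")
    best = None
    last_err = None
    for a0 in (1.0, 0.1, 0.5, 2.0):
        try:
            popt, _ = curve_fit(
                _decay, xs, ys, p0=(a0, 0.0),
                bounds=((1e-12, -0.999), (np.inf, np.inf)),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        rss = float(np.sum((_decay(xs, *popt) - ys) ** 2))
        if best is None or rss < best.rss:
            best = DecayFit(float(popt[0]), float(popt[1]), rss, True,
                            (a0, 0.0))
        if a0 == 1.0 and best is not None and best.rss < 1e-20:
            break
    if best is None:
        raise FitError(f"decay fit failed to converge: {last_err}")
    return best


def loess_trend(summaries: Sequence[GroupSummary],
                span: float = 0.75) -> pd.DataFrame:
    """Loess (locally weighted linear regression) of medians against size."""
    if not 0 < span <= 1:
        raise ParameterError("span must be in (0, 1]")
    if len(summaries) < 5:
        raise ParameterError("need >= 5 points for a Loess trend")
    xs = np.array([s.size for s in summaries], dtype=float)
    ys = np.array([s.median for s in summaries], dtype=float)
    fitted = lowess(ys, xs, frac=span, it=0, return_sorted=False)
    return pd.DataFrame({"x": xs, "median": ys, "smoothed": fitted})


def paired_similarity_comparison(embedding: Embedding,
                                 positive_pairs: Sequence[Pair],
                                 n: int, seed: int = 0,
                                 terms: Sequence[str] | None = None
                                 ) -> PairedSimilaritySample:
    """Cosines of n known pairs vs n random pairs over the same term universe.

    `terms` defaults to the embedding vocabulary restricted to the entity
    type of the positive pairs (all terms when untyped); the random arm
    excludes the positive pairs themselves.
    """
    present = [_canon(p) for p in positive_pairs
               if p[0] in embedding and p[1] in embedding and p[0] != p[1]]
    present = sorted(set(present))
    if len(present) < n:
        raise SamplingError(
            f"only {len(present)} positive pairs with embedding-present "
            f"members, requested {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(present), size=n, replace=False)
    positives = [present[i] for i in sorted(idx)]
    if terms is None:
        pair_types = {embedding.type_labels.get(t)
                      for p in present for t in p}
        if len(pair_types) == 1 and None not in pair_types:
            (etype,) = pair_types
            terms = sorted(t for t in embedding.vocab
                           if embedding.type_labels.get(t) == etype)
        else:
            terms = sorted(embedding.vocab)
    randoms = sample_random_pairs(terms, n, excluded_pairs=present,
                                  seed=seed + 1)
    pos_cos = np.array([embedding.cosine(a, b) for a, b in positives])
    rnd_cos = np.array([embedding.cosine(a, b) for a, b in randoms])
    return PairedSimilaritySample(positives, pos_cos, randoms, rnd_cos, n)


def drug_shared_target_analysis(embedding: Embedding,
                                targets: DrugTargetTable,
                                group_bounds: Sequence[int] = (0, 5, 9),
                                n: int = 50_000,
                                seed: int = 0) -> pd.DataFrame:
    """Quartiles of drug-pair cosines stratified by shared-target count.

    With the default bounds (0, 5, 9) the strata are: exactly 0 shared genes,
    1..5, and 6..9, mirroring the no-shared / <=5 / <=9 grouping. Up to n
    pairs are sampled per stratum. An empty stratum is reported with n=0.
    """
    if list(group_bounds) != sorted(set(group_bounds)):
        raise ParameterError("group_bounds must be strictly increasing")
    drugs = sorted(d for d in targets.targets if d in embedding)
    strata: dict[str, list[Pair]] = {}
    lows = [0] + [b + 1 for b in group_bounds[:-1]]
    names = [f"shared_{lo}_{hi}" if lo != hi else f"shared_{lo}"
             for lo, hi in zip(lows, group_bounds)]
    for name in names:
        strata[name] = []
    for a, b in itertools.combinations(drugs, 2):
        s = targets.shared(a, b)
        for name, lo, hi in zip(names, lows, group_bounds):
            if lo <= s <= hi:
                strata[name].append((a, b))
                break
    rng = np.random.default_rng(seed)
    rows = []
    for name in names:
        pairs = strata[name]
        if len(pairs) > n:
            idx = rng.choice(len(pairs), size=n, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        if pairs:
            values = np.array([embedding.cosine(a, b) for a, b in pairs])
            q1, med, q3 = np.percentile(values, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"group": name, "n": len(pairs), "requested_n": n,
                     "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows)
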