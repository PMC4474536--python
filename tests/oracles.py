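"""Independent brute-force recomputation of the reliability scores.

Works from raw ``(drug, gene, source, pmids)`` tuples with plain Python
loops — no shared code with the package's scoring path — so it can serve
as an oracle for randomized equivalence tests.
"""

from __future__ import annotations

import random


def brute_force_scores(
    raws: list[tuple[str, str, str, frozenset[str]]],
) -> dict[tuple[str, str], tuple[int, float]]:
    """(drug, gene) -> (source-concordance, reference-specificity sum)."""
    pairs_per_pmid: dict[str, set[tuple[str, str]]] = {}
    for drug, gene, _source, pmids in raws:
        for pmid in pmids:
            pairs_per_pmid.setdefault(pmid, set()).add((drug, gene))
    specificity = {}
    for pmid, pairs in pairs_per_pmid.items():
        f = len(pairs)
        d = len({drug for drug, _ in pairs})
        t = len({gene for _, gene in pairs})
        specificity[pmid] = d * t / (f * f)

    out: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for drug, gene, source, pmids in raws:
        sources, refs = out.setdefault((drug, gene), (set(), set()))
        sources.add(source)
        refs.update(pmids)
    return {
        key: (len(sources), sum(specificity[p] for p in refs))
        for key, (sources, refs) in out.items()
    }


def random_instance(
    seed: int, max_assocs: int = 50
) -> list[tuple[str, str, str, frozenset[str]]]:
    """A small random raw dataset with deliberately shared references."""
    rng = random.Random(seed)
    n = rng.randint(1, max_assocs)
    drugs = [f"d{i}" for i in range(rng.randint(1, 10))]
    genes = [f"g{i}" for i in range(rng.randint(1, 6))]
    sources = [f"s{i}" for i in range(rng.randint(1, 4))]
    pmid_pool = [f"p{i}" for i in range(rng.randint(1, 12))]
    raws = []
    for _ in range(n):
        n_refs = rng.randint(0, min(3, len(pmid_pool)))
        pmids = frozenset(rng.sample(pmid_pool, n_refs))
        raws.append((rng.choice(drugs), rng.choice(genes),
                     rng.choice(sources), pmids))
    return raws
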