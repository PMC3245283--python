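"""Hypergeometric term enrichment and two-list overlap significance.

Enrichment of a study gene set against a background is scored per term with
the upper-tail hypergeometric P(X >= k) (k study hits, K term genes in the
background, n study genes, N background genes); raw p < 0.01 flags
significance, with a BH-FDR column emitted for information only. The
two-list overlap test is the same tail with a fixed population size (default
12,000, the gene count of the comparison array platform).

Gene identifiers are matched case-insensitively with set semantics: a gene
hit by several DMRs still counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

DEFAULT_POPULATION = 12_000


def hypergeom_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N=big_n, K=big_k, draws=n)."""
    if not 0 <= k <= min(big_k, n):
        raise ValueError(f"impossible overlap k={k} for K={big_k}, n={n}")
    if big_k > big_n or n > big_n:
        raise ValueError("term/study size exceeds population")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, big_n, big_k, n))


@dataclass
class EnrichmentResult:
    term_id: str
    k: int
    big_k: int
    n: int
    big_n: int
    p_value: float
    genes: list[str]


def _norm(genes: Iterable[str]) -> set[str]:
    return {g.upper() for g in genes}


def enrich_terms(
    study_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """One row per term with >= 1 study hit, sorted by p.

    Columns: term_id, k, K, n, N, p_value, fdr, significant (p < threshold,
    strict), genes (space-joined study hits, Table-3 style). Terms are
    restricted to background genes; study genes must be a subset of the
    background.
    """
    background = _norm(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    study = _norm(study_genes)
    if not study <= background:
        missing = sorted(study - background)[:5]
        raise ValueError(
            f"study genes missing from background (e.g. {missing})"
        )
    results = []
    for term, genes in term_map.items():
        term_genes = _norm(genes) & background
        hits = sorted(term_genes & study)
        if not hits:
            continue
        p = hypergeom_tail(len(hits), len(term_genes), len(study), len(background))
        results.append(
            EnrichmentResult(term, len(hits), len(term_genes), len(study),
                             len(background), p, hits)
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    frame = pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "k": [r.k for r in results],
            "K": [r.big_k for r in results],
            "n": [r.n for r in results],
            "N": [r.big_n for r in results],
            "p_value": [r.p_value for r in results],
            "genes": [" ".join(r.genes) for r in results],
        }
    )
    if len(frame):
        frame["fdr"] = _bh(frame["p_value"].tolist())
        frame["significant"] = frame["p_value"] < p_threshold
    else:
        frame["fdr"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
    return frame


def _bh(p: list[float]) -> list[float]:
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    out = [0.0] * n
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = n - rank_from_top
        running = min(running, p[i] * n / rank)
        out[i] = running
    return out


@dataclass
class OverlapTestInput:
    list_a: set[str]
    list_b: set[str]
    population_n: int = DEFAULT_POPULATION

    def __post_init__(self) -> None:
        self.list_a = _norm(self.list_a)
        self.list_b = _norm(self.list_b)
        if max(len(self.list_a), len(self.list_b)) > self.population_n:
            raise ValueError("gene list larger than the population")


def overlap_test(inputs: OverlapTestInput) -> tuple[int, float]:
    """(observed overlap, P(X >= overlap)) under a hypergeometric with
    population N, draws |A| and successes |B|."""
    k = len(inputs.list_a & inputs.list_b)
    p = hypergeom_tail(k, len(inputs.list_b), len(inputs.list_a),
                       inputs.population_n)
    return k, p


def intersect_with_platform(
    dmr_genes: Iterable[str], platform_genes: Iterable[str]
) -> tuple[set[str], float]:
    """Subset of DMR genes present on an array platform and its percentage of
    the DMR gene set (unrounded; callers format)."""
    dmr = _norm(dmr_genes)
    platform = _norm(platform_genes)
    subset = dmr & platform
    fraction = 100.0 * len(subset) / len(dmr) if dmr else 0.0
    return subset, fraction


def write_enrichment(frame: pd.DataFrame, path: str) -> None:
    """TSV report with a commented header, p-values in scientific notation."""
    cols = ["term_id", "k", "K", "n", "N", "p_value", "fdr", "significant", "genes"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.term_id}\t{row.k}\t{row.K}\t{row.n}\t{row.N}\t"
                f"{row.p_value:.3e}\t{row.fdr:.3e}\t{int(row.significant)}\t"
                f"{row.genes}\n"
            )
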