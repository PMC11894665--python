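"""Over-representation analysis of bin protein sets.

One-sided hypergeometric tests of a foreground protein set (the proteins
behind the peptidoforms assigned to a bin) against the background universe
(all proteins with fitted models), per annotation term, with
Benjamini-Hochberg adjustment within each term category.  Term maps come
from GMT files (GO-style) or are built from a UniProt-like annotation
table using simple string rules for the five sulfation-context terms
(known_sY, Secreted, Transmembrane, Golgi, unlikely_sY).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

CUSTOM_TERMS = ("known_sY", "Secreted", "Transmembrane", "Golgi", "unlikely_sY")


@dataclass
class Term:
    term_id: str
    name: str
    category: str  # GO-BP | GO-CC | GO-MF | custom
    members: set[str]


TermMap = dict[str, Term]


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    category: str
    k: int  # foreground hits
    n: int  # foreground size
    K: int  # background hits
    N: int  # background size
    p_value: float
    p_adjusted: float

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n if self.n else 0.0


def read_gmt(path: str | Path, category: str = "GO-BP") -> TermMap:
    """Read a GMT file (term, description, tab-separated members)."""
    terms: TermMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {line!r}")
            term_id, name, *members = fields
            terms[term_id] = Term(term_id, name, category, set(m for m in members if m))
    return terms


def write_gmt(terms: TermMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms.values():
            fh.write("\t".join([t.term_id, t.name] + sorted(t.members)) + "\n")


ANNOTATION_COLUMNS = (
    "accession",
    "protein_name",
    "subcellular_location",
    "transmembrane",
    "known_sY",
)


def build_custom_terms(annotation_table: pd.DataFrame) -> TermMap:
    """Build the five sulfation-context terms from an annotation table.

    Rules (case-insensitive substring matches):

    - known_sY: rows flagged as having a known sulfotyrosine.
    - Secreted: "secreted" appears in the subcellular location.
    - Transmembrane: the transmembrane column is non-empty.
    - Golgi: "golgi" appears in the protein name or subcellular location.
    - unlikely_sY: complement of the union of the other four.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation_table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    df = annotation_table.fillna("")
    acc = df["accession"].astype(str)
    loc = df["subcellular_location"].astype(str).str.lower()
    name = df["protein_name"].astype(str).str.lower()
    tm = df["transmembrane"].astype(str).str.strip()
    sy = df["known_sY"].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "y"))

    known = set(acc[sy])
    secreted = set(acc[loc.str.contains("secreted")])
    transmembrane = set(acc[tm != ""])
    golgi = set(acc[name.str.contains("golgi") | loc.str.contains("golgi")])
    tagged = known | secreted | transmembrane | golgi
    unlikely = set(acc) - tagged

    sets = {
        "known_sY": known,
        "Secreted": secreted,
        "Transmembrane": transmembrane,
        "Golgi": golgi,
        "unlikely_sY": unlikely,
    }
    return {
        t: Term(t, t, "custom", members) for t, members in sets.items()
    }


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the one-sided ORA p-value.

    N is the background size, K the background hits for the term, n the
    foreground size, k the observed foreground hits.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible configuration k={k} n={n} K={K} N={N}")
    if k > K:
        logger.warning("k=%d exceeds background hits K=%d; returning p=0", k, K)
        return 0.0
    if k == 0:
        return 1.0
    # survival function P(X > k-1) = P(X >= k), computed stably by scipy
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest down, cap at 1
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def run_ora(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: TermMap,
    q_cutoff: float | None = 0.1,
    min_set_size: int = 1,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric ORA of foreground vs background per term.

    Term membership is intersected with the background universe; terms
    with fewer than ``min_set_size`` background members are skipped.  BH
    adjustment is performed within each term category independently.
    Results are filtered to p_adjusted <= q_cutoff when a cutoff is set.
    """
    bg = set(background)
    fg = set(foreground) & bg
    if set(foreground) - bg:
        logger.warning(
            "%d foreground proteins outside the background were dropped",
            len(set(foreground) - bg),
        )
    if not fg:
        logger.warning("empty foreground; no enrichment computed")
        return []
    N, n = len(bg), len(fg)
    prelim: list[EnrichmentResult] = []
    for t in terms.values():
        members = t.members & bg
        if len(members) < min_set_size:
            continue
        K = len(members)
        k = len(members & fg)
        p = hypergeometric_upper_tail(k, n, K, N)
        prelim.append(
            EnrichmentResult(t.term_id, t.name, t.category, k, n, K, N, p, p)
        )
    # BH within each category separately
    for category in sorted({r.category for r in prelim}):
        group = [r for r in prelim if r.category == category]
        adjusted = bh_adjust([r.p_value for r in group])
        for r, adj in zip(group, adjusted):
            r.p_adjusted = adj
    if q_cutoff is not None:
        prelim = [r for r in prelim if r.p_adjusted <= q_cutoff]
    return sorted(prelim, key=lambda r: (r.category, r.p_adjusted, r.term_id))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "gene_ratio": r.gene_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
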