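"""Fisher-exact gene-set over-representation with FDR control.

Replaces a proprietary pathway engine with user-supplied GMT catalogs: each
set is tested for over-representation of differentially expressed genes by a
one-sided hypergeometric (Fisher exact) test against a background universe
(the detected probes of the contrast), with Benjamini–Hochberg adjustment
across sets.  Per-set direction composition (percent up / down / unchanged)
supports stacked-bar summaries of shared pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rapalife.transcriptome_de import DEFilter, filter_de


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe of identifiers."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self):
        uni = set(self.universe)
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            extra = set(members) - uni
            if extra:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: {sorted(extra)[:5]}")

    def harmonized(self, universe: list[str]) -> "GeneSetCollection":
        """Restrict every set to a new universe, dropping empty sets."""
        uni = set(universe)
        sets = {}
        for name, members in self.sets.items():
            kept = [m for m in members if m in uni]
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=list(universe))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT catalog (tab-separated: name, description, members...).

    Duplicate members within a line are deduplicated with a warning; an
    empty set or malformed line raises with its line number.  The universe
    is the union of all members.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need name, "
                                 "description and at least one member)")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: empty gene set at line {lineno}")
            seen, unique = set(), []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) < len(members):
                warnings.warn(f"{path}: duplicate members in set {name!r} "
                              f"(line {lineno}) were deduplicated")
            sets[name] = unique
    universe = sorted({m for members in sets.values() for m in members})
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def fisher_enrichment(de_genes, collection: GeneSetCollection,
                      universe=None) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per gene set.

    For a universe of size M with N DE genes, a set of size n and overlap k,
    the p-value is the hypergeometric upper tail P(X >= k).  B-H adjustment
    runs across all tested sets; ``significant`` marks adjusted p < 0.05.
    """
    universe = list(collection.universe if universe is None else universe)
    uni = set(universe)
    de = set(de_genes)
    if not de <= uni:
        raise ValueError("DE genes must be a subset of the universe")
    if not de:
        warnings.warn("empty DE list: all enrichment p-values are 1")
    M, N = len(uni), len(de)
    rows = []
    for name, members in collection.sets.items():
        in_uni = [m for m in members if m in uni]
        n = len(in_uni)
        k = len(de & set(in_uni))
        p = float(stats.hypergeom.sf(k - 1, M, N, n)) if n else 1.0
        rows.append((name, k, N - k, n - k, M - N - n + k, p))
    df = pd.DataFrame(rows, columns=["set", "de_in_set", "de_out_set",
                                     "nonde_in_set", "nonde_out_set", "p"]).set_index("set")
    df["adjusted_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["adjusted_p"] < 0.05
    return df.sort_values("adjusted_p")


def direction_summary(members: list[str], contrast: pd.DataFrame,
                      flt: DEFilter) -> dict[str, float]:
    """Percent of a gene set's members up-, down- and un-changed in a contrast.

    Percentages are over the set's size within the contrast universe and sum
    to 100 within rounding.
    """
    members = [m for m in members if m in contrast.index]
    if not members:
        return {"pct_up": 0.0, "pct_down": 0.0, "pct_unchanged": 100.0}
    sig = filter_de(contrast.loc[members], flt)
    n = len(members)
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    return {
        "pct_up": 100.0 * n_up / n,
        "pct_down": 100.0 * n_down / n,
        "pct_unchanged": 100.0 * (n - n_up - n_down) / n,
    }


def enrichment_report(de_genes, collection: GeneSetCollection, contrast: pd.DataFrame,
                      flt: DEFilter, universe=None) -> pd.DataFrame:
    """Enrichment table with direction composition, ranked by adjusted p."""
    enr = fisher_enrichment(de_genes, collection, universe)
    comp = {name: direction_summary(collection.sets[name], contrast, flt)
            for name in enr.index}
    comp_df = pd.DataFrame(comp).T
    return enr.join(comp_df)
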