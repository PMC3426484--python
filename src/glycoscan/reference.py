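"""Reference summary statistics from the published HGDP selection scan of
the asparagine N-glycosylation pathway.

These small tables ship with the package and hold the printed per-gene hit
lists (raw and Bonferroni-corrected gene-level p-values), the
upstream/downstream event counts, and the centrality Mann-Whitney summaries
(rank sums, U, Z, p). They are used as *inputs* to arithmetic
reconstruction checks -- e.g. re-deriving U from the printed rank sums, or
the Bonferroni factor from the number of groups and methods -- not as
substitutes for computation on genotype data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Bonferroni multiplier of the original study: 7 continental groups x 2 methods
N_GROUPS = 7
N_METHODS = 2


def _load(name: str) -> pd.DataFrame:
    with resources.files("glycoscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_published_gene_hits() -> pd.DataFrame:
    """Per-gene significant hits: statistic, sub_pathway, gene,
    continental_group, p_value, corrected_p."""
    return _load("published_gene_hits.tsv")


def load_published_part_counts() -> pd.DataFrame:
    """Upstream/downstream gene and event counts per statistic."""
    return _load("published_part_counts.tsv")


def load_published_centrality_tests() -> pd.DataFrame:
    """Centrality-association Mann-Whitney summaries (rank sums, U, Z, p)."""
    return _load("published_centrality_tests.tsv")
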