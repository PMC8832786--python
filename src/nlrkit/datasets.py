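"""Bundled reference tables for the *H. villosa* NLR survey.

Three small tab-separated tables ship with the package so the
table-level operations can be exercised without any downloads:

* ``hv_chromosome_locations``   — physically mapped NLRs: per-genome best
  chromosomes (wheat, barley, *Ae. tauschii*) and the *H. villosa*
  chromosome arm established with translocation lines.
* ``hv_r_gene_orthologues``     — catalog NLRs matching cloned R genes
  (*Mla1*/*Sr50*, *Pm3b*, *Sr45*, *Yr7*, *RCR1*, *Sr35*, *Lr1*, *Pm2*)
  with percent identity/coverage; *Mla*-locus rows carry the barley 1H
  anchor position in Mb.
* ``grass_integrated_domains``  — integrated-domain presence across seven
  grass genomes (VV, AABBDD, AA, DD, HH, Bd, Os).
* ``hv_catalog_counts``         — headline catalog counts (completeness
  categories, Type I–V class sizes, indel-marker totals).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("nlrkit").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_chromosome_locations() -> pd.DataFrame:
    return _load("hv_chromosome_locations.tsv")


def load_r_gene_orthologues() -> pd.DataFrame:
    return _load("hv_r_gene_orthologues.tsv")


def load_integrated_domains() -> pd.DataFrame:
    return _load("grass_integrated_domains.tsv")


def load_catalog_counts() -> dict[str, int]:
    df = _load("hv_catalog_counts.tsv")
    return dict(zip(df["key"], df["value"].astype(int)))
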