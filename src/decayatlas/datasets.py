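"""Packaged example data.

``load_toy20`` returns a tiny hand-built 20-gene dataset whose expected
behaviour under every expression filter is documented line by line in
``data/toy20/README.md``: library totals of 1e9 make FPKM equal counts
divided by length, so all expected outcomes are hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .quantify import CountMatrix

__all__ = ["Toy20", "load_toy20"]


@dataclass
class Toy20:
    gene_lengths: pd.DataFrame
    exonic: CountMatrix
    intronic: CountMatrix
    rip_input: CountMatrix
    rip: CountMatrix


def _read(name: str, index_col: str = "gene_id") -> pd.DataFrame:
    ref = resources.files("decayatlas").joinpath(f"data/toy20/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#").set_index(index_col)


def load_toy20() -> Toy20:
    lengths = _read("genes.tsv")
    totals = _read("totals.tsv", index_col="sample_id")["library_total"]
    return Toy20(
        gene_lengths=lengths,
        exonic=CountMatrix(
            region="exonic",
            counts=_read("counts_exonic.tsv"),
            totals=totals[["liver_exon"]],
        ),
        intronic=CountMatrix(
            region="intronic",
            counts=_read("counts_intronic.tsv"),
            totals=totals[["liver_intron"]],
        ),
        rip_input=CountMatrix(
            region="exonic",
            counts=_read("counts_rip_input.tsv"),
            totals=totals[["rip_input"]],
        ),
        rip=CountMatrix(
            region="exonic",
            counts=_read("counts_rip.tsv"),
            totals=totals[["rip_pulldown"]],
        ),
    )
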