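"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .tables import ContingencyTable, read_counts

__all__ = ["load_renex_consensus"]


def load_renex_consensus() -> ContingencyTable:
    """The published 3x3 cross-classification of 185 kidneys read by the
    RENEX expert system (rows) and the consensus of three experts
    (columns), categories non-obstructed / equivocal / obstructed."""
    path = resources.files("agreemod.data").joinpath("renex_consensus_counts.csv")
    with resources.as_file(path) as p:
        return read_counts(
            p, categories=("non-obstructed", "equivocal", "obstructed")
        )
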