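"""Published genome-scale counts for the cotton LRR-RLK family.

These tables hold printed survey results — per-species identification
totals, subfamily membership counts, and tandem-duplication counts — and
serve as inputs for recomputing the derived statistics (percentage shares,
XI/XII tandem shares, scaffold fractions) with the package's own table
arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_subfamily_counts",
    "load_tandem_counts",
    "load_identified_counts",
    "tandem_counts_wide",
]

_SPECIES = ["A_thaliana", "G_arboreum", "G_barbadense", "G_hirsutum",
            "G_raimondii"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("lrrkit") / "data" / "reference" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_subfamily_counts() -> pd.DataFrame:
    """Subfamily × species membership counts (21 rows, 5 species)."""
    return _read("subfamily_counts.tsv", index_col=0)


def load_tandem_counts() -> pd.DataFrame:
    """Long-format per-subfamily tandem gene/set counts per species."""
    return _read("tandem_counts.tsv")


def tandem_counts_wide(value: str = "n_sets") -> pd.DataFrame:
    """Pivot tandem counts to subfamily × species (absent → 0)."""
    df = load_tandem_counts()
    return (df.pivot(index="subfamily", columns="species", values=value)
            .fillna(0).astype(int))


def load_identified_counts() -> pd.DataFrame:
    """Per-species identification totals and scaffold-located counts."""
    return _read("identified_counts.tsv", index_col=0)
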