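"""Bundled reference tables.

``load_tac_de_summary`` returns the published per-miRNA differential
expression summary (log2 fold change and exact-test p-value, TAC vs sham)
for the top-changing miRNAs of the mitochondrial fraction in the
pressure-overload heart-failure study the pipeline re-implements, at 4 and
8 weeks after surgery. Useful for exercising the threshold-calling logic on
real printed statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_tac_de_summary"]


def load_tac_de_summary() -> pd.DataFrame:
    """Published DE summary statistics: columns pair, mirna, log2_fc, p_value."""
    ref = resources.files("mitomir.data").joinpath("tac_mito_de_summary.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
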