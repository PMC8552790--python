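"""Bundled reference tables.

``nsclc_sde_mirnas.tsv`` is the curated differential-expression summary of
15 significantly differentially expressed miRNAs from an NSCLC tumor vs
paraneoplastic-tissue discovery screen (TCGA + GEO intersection): per-miRNA
two-sided p-value, log2 fold change (tumor over normal), signal-to-noise
score and regulation call.  It serves as a worked-example input for the
volcano/SNR screening thresholds.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_nsclc_sde_table() -> pd.DataFrame:
    """The 15-miRNA NSCLC reference DE table (index: miRNA ID; columns:
    pvalue, log2fc, snr, status)."""
    with resources.files(__package__).joinpath("nsclc_sde_mirnas.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df
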