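import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def two_rep_bins():
    """A 7-bin, two-replicate manifest with strictly increasing mean times."""
    rows = []
    for rep, offset in (("A", 0.0), ("B", 0.5)):
        for b in range(1, 8):
            rows.append(
                {
                    "replicate": rep,
                    "bin_index": b,
                    "mean_survival_h": 12.0 * b + offset,
                    "n_individuals": 200,
                }
            )
    df = pd.DataFrame(rows)
    df["sample"] = df["replicate"] + df["bin_index"].astype(str)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_counts(bins, ref_by_sample, alt_by_sample, chrom="2L", pos=100):
    """One variant's count rows across the given bin samples."""
    rows = []
    for sample in bins["sample"]:
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "T",
                "sample": sample,
                "ref_reads": ref_by_sample[sample],
                "alt_reads": alt_by_sample[sample],
            }
        )
    return pd.DataFrame(rows)
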