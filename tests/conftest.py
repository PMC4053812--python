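import numpy as np
import pandas as pd
import pytest

from methylodyn import FragmentTrack, GeneTable, Methylome


def make_methylome(sites, sample="s", manifest=None):
    """sites: list of (chrom, pos, meth, total)."""
    df = pd.DataFrame(sites, columns=["chrom", "pos", "meth", "total"])
    return Methylome(df, sample, manifest)


@pytest.fixture
def tiny_methylome():
    return make_methylome(
        [("chr1", 100, 5, 10), ("chr1", 150, 10, 10), ("chr1", 300, 0, 10)]
    )


@pytest.fixture
def two_exon_gene():
    df = pd.DataFrame(
        [
            {
                "gene_id": "g1",
                "chrom": "chr1",
                "strand": "+",
                "tx_start": 1000,
                "tx_end": 5000,
                "cds_start": 1500,
                "cds_end": 4500,
                "exon_starts": (1000, 3000),
                "exon_ends": (2000, 5000),
            }
        ]
    )
    return GeneTable(df)


def make_track(counts, klasses=None, chrom="c", viewpoint=0):
    counts = list(counts)
    if klasses is None:
        klasses = ["regular"] * len(counts)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(len(counts)) * 1000 + 500,
            "klass": klasses,
            "count": counts,
        }
    )
    return FragmentTrack(df, chrom, viewpoint)
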