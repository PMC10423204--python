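import numpy as np
import pandas as pd
import pytest

from fishloop.trace_io import LocusAnnotation, TraceSet, annotation_from_frame, traceset_from_frame


def make_annotation(n_loci, resolution=25_000, start0=1, region="r1", chrom="chr1") -> LocusAnnotation:
    starts = start0 + resolution * np.arange(n_loci)
    return annotation_from_frame(
        pd.DataFrame(
            {
                "region_id": region,
                "locus_id": np.arange(n_loci),
                "chrom": chrom,
                "start": starts,
                "end": starts + resolution - 1,
            }
        )
    )


def make_traces(records, ann) -> TraceSet:
    """records: iterable of (allele_id, locus_id, x, y, z) within ann's sole region."""
    region = ann.regions[0]
    df = pd.DataFrame(records, columns=["allele_id", "locus_id", "x", "y", "z"])
    df.insert(1, "region_id", region)
    return traceset_from_frame(df, ann)


@pytest.fixture
def ann9():
    return make_annotation(9, resolution=25_000)


@pytest.fixture
def ann41_5kb():
    return make_annotation(41, resolution=5_000, start0=34_600_001, region="sox2", chrom="chr3")
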