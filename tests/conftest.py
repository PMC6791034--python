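import numpy as np
import pysam
import pytest

from tescope.core_io import HSP, BASE_CODE, ConsensusLibrary, TE_FAMILY, SINGLE_COPY_GENE
from tescope.sim import random_dna


def make_hsp(
    read_id="r1",
    contig="TE",
    ref_start=0,
    ref_end=None,
    read_start=0,
    read_end=None,
    strand="+",
    mapq=60,
    read_length=100,
    ambiguous=False,
    ref_seq=None,
    read_bases=None,
):
    """Construct an HSP whose per-base evidence matches its intervals.

    ``read_bases`` (a string as long as the ref interval) overrides the
    reference bases; by default the HSP is a perfect match to ``ref_seq``.
    """
    if ref_end is None:
        ref_end = ref_start + 50
    if read_end is None:
        read_end = read_start + (ref_end - ref_start)
    n = ref_end - ref_start
    if read_bases is None:
        read_bases = ref_seq[ref_start:ref_end] if ref_seq else "A" * n
    codes = np.array([BASE_CODE[b] for b in read_bases], dtype=np.uint8)
    return HSP(
        read_id=read_id,
        contig=contig,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=read_start,
        read_end=read_end,
        strand=strand,
        mapq=mapq,
        read_length=read_length,
        ambiguous=ambiguous,
        match_ref_pos=np.arange(ref_start, ref_end, dtype=np.int32),
        match_base=codes,
    )


@pytest.fixture
def hsp_factory():
    return make_hsp


@pytest.fixture
def small_library():
    rng = np.random.default_rng(7)
    return ConsensusLibrary(
        {
            "TE": (random_dna(600, rng), TE_FAMILY),
            "gene1": (random_dna(300, rng), SINGLE_COPY_GENE),
        }
    )


def write_sam(path, records, contigs):
    """Write SAM records given as dicts; contigs is {name: length}."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs.items()],
    }
    names = list(contigs)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in records:
            rec = pysam.AlignedSegment()
            rec.query_name = r["name"]
            rec.flag = r.get("flag", 0)
            if not rec.is_unmapped:
                rec.reference_id = names.index(r["contig"])
                rec.reference_start = r["pos"]
                rec.mapping_quality = r.get("mapq", 60)
                rec.cigarstring = r["cigar"]
            rec.query_sequence = r["seq"]
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            fh.write(rec)
    return path


@pytest.fixture
def sam_writer():
    return write_sam
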