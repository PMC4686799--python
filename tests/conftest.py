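import pandas as pd
import pysam
import pytest

from cfdnafrag import SimulationConfig, generate_fragments, generate_nucleosome_map

SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


def make_read(name: str, pos: int, mate_pos: int, flag: int,
              read_len: int = 100) -> pysam.AlignedSegment:
    """A minimal aligned read for pairing tests."""
    a = pysam.AlignedSegment(SAM_HEADER)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = pos
    a.cigarstring = f"{read_len}M"
    a.flag = flag
    a.next_reference_id = 0
    a.next_reference_start = mate_pos
    a.query_sequence = "A" * read_len
    a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
    return a


def make_pair(name: str, start: int, end: int, read_len: int = 100):
    """Two proper-pair reads whose fragment spans [start, end)."""
    left = make_read(name, start, end - read_len, 99, read_len)
    right = make_read(name, end - read_len, start, 147, read_len)
    return [left, right]


@pytest.fixture(scope="session")
def default_sim():
    """A mid-sized simulation shared by read-only tests."""
    cfg = SimulationConfig(seed=1234, region_length=400_000, n_fragments=80_000)
    nmap = generate_nucleosome_map(cfg)
    frags = generate_fragments(nmap, cfg)
    return cfg, nmap, frags


def frame_from_intervals(intervals, chrom="chr1"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["length"] = df["end"] - df["start"]
    return df
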