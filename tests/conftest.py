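import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from esmatch.io_formats import NucleotideSequence, SectoredTranscript
from esmatch.segmentation import RnaSegment


def make_seq(residues: str, seq_id: str = "seq") -> NucleotideSequence:
    return NucleotideSequence(seq_id, residues)


def make_segment(residues: str, segment_id: str = "ESL7", group: str = "ESL") -> RnaSegment:
    return RnaSegment(segment_id, group, NucleotideSequence(segment_id, residues))


def make_transcript(
    utr5: str = "AAAAAAAAAA",
    cds: str = "AAAAAAAAAA",
    utr3: str = "AAAAAAAAAA",
    transcript_id: str = "t1",
) -> SectoredTranscript:
    return SectoredTranscript(
        transcript_id=transcript_id,
        utr5=NucleotideSequence(f"{transcript_id}|utr5", utr5),
        cds=NucleotideSequence(f"{transcript_id}|cds", cds),
        utr3=NucleotideSequence(f"{transcript_id}|utr3", utr3),
    )


def random_rna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAU"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
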