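import numpy as np
import pytest

from cnvkin.calls import CNVCall


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_call(
    start,
    end,
    sample="S1",
    chrom="chr1",
    cnv_type="deletion",
    n_snps=20,
    confidence=30.0,
    caller="A",
):
    return CNVCall(
        sample_id=sample,
        chrom=chrom,
        start=start,
        end=end,
        type=cnv_type,
        n_snps=n_snps,
        confidence=confidence,
        caller=caller,
    )


def random_calls(rng, n, sample="S1", caller="A", max_pos=10_000, chroms=("chr1", "chr2")):
    """Small random call sets with small coordinates (oracle-friendly)."""
    calls = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, max_pos))
        length = int(rng.integers(1, max_pos // 4))
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        calls.append(
            make_call(
                start,
                start + length,
                sample=sample,
                chrom=chrom,
                cnv_type=cnv_type,
                n_snps=int(rng.integers(1, 50)),
                confidence=float(rng.uniform(1, 100)),
                caller=caller,
            )
        )
    return calls
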