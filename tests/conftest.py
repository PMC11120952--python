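import numpy as np
import pytest

from pavscape.core import PAVRecord


@pytest.fixture
def make_record():
    """Factory for valid PAVRecords with a single dummy sample."""

    def _make(chrom="chr1", start=10_000, end=12_000, svtype="DEL",
              svlen=None, caller="callerA", filt="PASS", genotypes=None,
              record_id=""):
        if svlen is None:
            svlen = -(end - start) if svtype == "DEL" else 100
        if genotypes is None:
            genotypes = np.array([1], dtype=np.int8)
        rec = PAVRecord(chrom=chrom, start=start, end=end, svtype=svtype,
                        svlen=svlen, caller=caller, filter=filt,
                        genotypes=np.asarray(genotypes, dtype=np.int8),
                        record_id=record_id)
        rec.validate()
        return rec

    return _make


def random_records(rng, n, n_samples=1, chroms=("chr1", "chr2"),
                   span=50_000, max_size=3000):
    """Random valid PAV records packed densely enough to force clusters."""
    records = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = "DEL" if rng.random() < 0.8 else "INS"
        start = int(rng.integers(1, span))
        size = int(rng.integers(50, max_size))
        if svtype == "DEL":
            end, svlen = start + size, -size
        else:
            end, svlen = start, size
        geno = rng.integers(-1, 2, size=n_samples).astype(np.int8)
        records.append(PAVRecord(
            chrom=chrom, start=start, end=end, svtype=svtype, svlen=svlen,
            caller="callerA" if i % 2 else "callerB", filter="PASS",
            genotypes=geno, record_id=f"r{i:04d}"))
    return records
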