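import numpy as np
import pandas as pd
import pytest

from tglocate import _dna
from tglocate.genome import TransgeneConstruct
from tglocate.pipeline import SimConfig, build_case, simulate_case_reads, stage_and_score
from tglocate.simulate import make_host_genome
from tglocate.staged import ORPHAN_COLUMNS


@pytest.fixture(scope="session")
def tiny_host():
    """100 kb repeat-free host genome."""
    return make_host_genome(1, 100_000, 0.0, seed=11)


@pytest.fixture(scope="session")
def repeat_host():
    """200 kb host with ~30% repeat content (6 kb units)."""
    return make_host_genome(1, 200_000, 0.3, 6000, seed=12)


@pytest.fixture(scope="session")
def tg_construct():
    rng = np.random.default_rng(13)
    seq = _dna.decode(_dna.from_codes(_dna.random_codes(rng, 10_000)))
    return TransgeneConstruct(seq, "transgene")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        host_len=200_000,
        repeat_fraction=0.1,
        tg_len=10_000,
        copy_number=3,
        first_copy_truncation=500,
        coverage=8.0,
        error_rate=0.0,
        low_quality_read_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """One shared end-to-end staging run on a 200 kb hemizygous case."""
    case = build_case(small_config, seed=21)
    pairset = simulate_case_reads(case, seed=22)
    report, table, filtered, scores, orphan_idx, orphan_mate = stage_and_score(
        pairset, case.tg, case.host, small_config, seed=23
    )
    return {
        "case": case,
        "pairset": pairset,
        "report": report,
        "table": table,
        "filtered": filtered,
        "scores": scores,
        "orphan_idx": orphan_idx,
        "orphan_mate": orphan_mate,
    }


def random_orphan_table(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_pos: int = 10_000,
    mapq_choices=(0, 19, 20, 60),
) -> pd.DataFrame:
    """Random but schema-valid orphan table for scoring-stage tests."""
    ci = rng.integers(0, len(chroms), size=n)
    df = pd.DataFrame(
        {
            "name": [f"r{i:05d}" for i in range(n)],
            "host_chrom": np.array(chroms, dtype=object)[ci],
            "host_pos": rng.integers(1, max_pos + 1, size=n),
            "host_strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "host_mapq": rng.choice(mapq_choices, size=n),
            "host_cigar": "100M",
            "tg_name": "transgene",
            "tg_pos": rng.integers(1, 5000, size=n),
            "tg_strand": "+",
            "tg_mapq": rng.choice(mapq_choices, size=n),
            "read_len": 100,
            "dtn": np.nan,
            "flags_hex": "0x0",
        }
    )[ORPHAN_COLUMNS]
    return df


def dtn_bruteforce(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-successor oracle for the DTN metric.

    Record i gets 0 when a same-coordinate record follows it in input order,
    else the gap to the smallest strictly greater coordinate on the same
    chromosome, else +inf.
    """
    n = len(pos)
    idx = np.arange(n)
    same = chrom[:, None] == chrom[None, :]
    dup_later = same & (pos[None, :] == pos[:, None]) & (idx[None, :] > idx[:, None])
    has_dup = dup_later.any(axis=1)
    greater = np.where(same & (pos[None, :] > pos[:, None]), pos[None, :], np.inf)
    nxt = greater.min(axis=1)
    return np.where(has_dup, 0.0, nxt - pos)
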