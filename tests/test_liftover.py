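"""Chain parsing and interval lifting against per-base walking oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from targetlink.intervals import GenomicInterval
from targetlink.liftover import (ChainError, LiftStatus, invert_chain,
                                 lift_interval, read_chain, write_chain)

from _oracles import chain_file_base_map, lift_fraction_by_walk

IDENTITY = "chain 100 chr1 1000000 + 0 1000 chr1 1000000 + 0 1000 1\n1000\n\n"


def _write(tmp_path, text, name="c.chain"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_identity_chain_parses(tmp_path):
    chains = read_chain(_write(tmp_path, IDENTITY))
    assert len(chains) == 1
    c = chains[0]
    assert c.blocks == ((1000, 0, 0),) and not c.strand_flip
    assert c.source_span == GenomicInterval("chr1", 0, 1000)


def test_inconsistent_block_arithmetic_rejected(tmp_path):
    bad = "chain 100 chr1 1000000 + 0 1000 chr1 1000000 + 0 1000 1\n900\n\n"
    with pytest.raises(ChainError, match="chain 1"):
        read_chain(_write(tmp_path, bad))


@pytest.mark.parametrize(
    "mutant",
    [
        "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 50 10\n201\n\n",  # size off by one
        "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 51 10\n200\n\n",  # source gap off
        "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 50 11\n200\n\n",  # target gap off
        "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 50 10\n200 1 0\n\n",  # trailing gap
        "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 -1 10\n200\n\n",  # negative gap
    ],
)
def test_every_block_arithmetic_mutation_rejected(tmp_path, mutant):
    valid = "chain 1 chr1 2000 + 0 350 chr2 2000 + 0 310 9\n100 50 10\n200\n\n"
    read_chain(_write(tmp_path, valid, "ok.chain"))  # baseline accepted
    with pytest.raises(ChainError):
        read_chain(_write(tmp_path, mutant, "bad.chain"))


def test_two_block_chain_matches_per_base_oracle(tmp_path):
    text = "chain 1 chr1 2000 + 0 350 chr2 2000 + 5 315 9\n100 50 10\n200\n\n"
    path = _write(tmp_path, text)
    chain = read_chain(path)[0]
    oracle = chain_file_base_map(path)
    for pos in range(0, 360):
        expected = oracle.get(("chr1", pos))
        got = chain.map_base(pos)
        assert got == (expected[1] if expected else None)


def test_negative_strand_chain_normalized(tmp_path):
    text = "chain 1 chr1 1000 + 100 200 chrT 500 - 100 200 7\n100\n\n"
    path = _write(tmp_path, text)
    chain = read_chain(path)[0]
    assert chain.strand_flip
    assert chain.target_span == GenomicInterval("chrT", 300, 400)
    oracle = chain_file_base_map(path)
    for pos in range(100, 200):
        assert chain.map_base(pos) == oracle[("chr1", pos)][1]
    res = lift_interval(GenomicInterval("chr1", 100, 200, "+"), [chain])
    assert res.status is LiftStatus.MAPPED
    assert res.mapped_interval == GenomicInterval("chrT", 300, 400, "-")


def test_lift_identity_examples(tmp_path):
    chains = read_chain(_write(tmp_path, IDENTITY))
    res = lift_interval(GenomicInterval("chr1", 100, 200), chains)
    assert res.status is LiftStatus.MAPPED
    assert res.mapped_interval == GenomicInterval("chr1", 100, 200)
    assert res.mapped_fraction == 1.0


def test_lift_interval_in_gap_unmapped(tmp_path):
    text = "chain 1 chr1 5000 + 0 2000 chr2 5000 + 0 1990 9\n1000 10 0\n990\n\n"
    chains = read_chain(_write(tmp_path, text))
    res = lift_interval(GenomicInterval("chr1", 1000, 1010), chains)
    assert res.status is LiftStatus.UNMAPPED and res.mapped_fraction == 0.0
    assert res.mapped_interval is None


def test_lift_partial_below_threshold_fraction_from_oracle(tmp_path):
    text = "chain 1 chr1 5000 + 0 2000 chr2 5000 + 0 1990 9\n1000 10 0\n990\n\n"
    path = _write(tmp_path, text)
    chains = read_chain(path)
    iv = GenomicInterval("chr1", 950, 1050)  # 90 of 100 bases in blocks
    res = lift_interval(iv, chains, min_match=0.95)
    assert res.status is LiftStatus.PARTIAL
    frac, _ = lift_fraction_by_walk(chain_file_base_map(path), "chr1", 950, 1050)
    assert res.mapped_fraction == frac == 0.90


def test_lift_split_across_chains(tmp_path):
    text = (
        "chain 1 chr1 5000 + 0 100 chr2 5000 + 0 100 1\n100\n\n"
        "chain 1 chr1 5000 + 100 200 chr3 5000 + 0 100 2\n100\n\n"
    )
    chains = read_chain(_write(tmp_path, text))
    res = lift_interval(GenomicInterval("chr1", 50, 150), chains)
    assert res.status is LiftStatus.SPLIT
    assert res.mapped_interval is None and res.mapped_fraction == 1.0


def test_min_match_argument_validated(tmp_path):
    chains = read_chain(_write(tmp_path, IDENTITY))
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            lift_interval(GenomicInterval("chr1", 0, 10), chains, min_match=bad)


@given(st.integers(0, 990), st.integers(1, 10))
def test_identity_chain_is_identity_property(start, length):
    from targetlink.liftover import ChainAlignment

    chain = ChainAlignment(
        source_assembly="chr1", target_assembly="chr1",
        source_span=GenomicInterval("chr1", 0, 1000),
        target_span=GenomicInterval("chr1", 0, 1000),
        source_size=1000000, target_size=1000000,
        blocks=((1000, 0, 0),), chain_id="1",
    )
    iv = GenomicInterval("chr1", start, start + length)
    res = lift_interval(iv, [chain])
    assert res.status is LiftStatus.MAPPED and res.mapped_interval == iv


def _random_chain_text(rng):
    """Three multi-block chains with disjoint source spans, one flipped."""
    parts = []
    starts = [0, 40000, 75000]
    for i, s0 in enumerate(starts):
        n_blocks = int(rng.integers(2, 6))
        sizes = rng.integers(50, 2000, n_blocks)
        dts = np.append(rng.integers(0, 500, n_blocks - 1), 0)
        dqs = np.append(rng.integers(0, 500, n_blocks - 1), 0)
        t_len = int((sizes + dts).sum())
        q_len = int((sizes + dqs).sum())
        flip = i == 1
        q_start = int(rng.integers(0, 1000))
        strand = "-" if flip else "+"
        header = (f"chain 1 chr1 200000 + {s0} {s0 + t_len} chrQ{i} 300000 "
                  f"{strand} {q_start} {q_start + q_len} {i}")
        lines = [header]
        for j in range(n_blocks):
            if j < n_blocks - 1:
                lines.append(f"{sizes[j]} {dts[j]} {dqs[j]}")
            else:
                lines.append(f"{sizes[j]}")
        parts.append("\n".join(lines) + "\n")
    return "\n".join(parts)


def test_random_chains_fraction_equals_per_base_oracle(tmp_path):
    rng = np.random.default_rng(42)
    path = _write(tmp_path, _random_chain_text(rng))
    chains = read_chain(path)
    oracle = chain_file_base_map(path)
    for _ in range(300):
        start = int(rng.integers(0, 100000))
        length = int(rng.integers(1, 500))
        iv = GenomicInterval("chr1", start, start + length)
        res = lift_interval(iv, chains)
        frac, images = lift_fraction_by_walk(oracle, "chr1", start, start + length)
        assert res.mapped_fraction == pytest.approx(frac, abs=0)
        if res.status in (LiftStatus.MAPPED, LiftStatus.PARTIAL):
            positions = [p for p in images if p != "MULTI"]
            chroms = {c for c, _ in positions}
            assert chroms == {res.mapped_interval.chrom}
            lo = min(p for _, p in positions)
            hi = max(p for _, p in positions)
            assert (res.mapped_interval.start, res.mapped_interval.end) == (lo, hi + 1)


def test_invert_chain_round_trips_per_base(tmp_path):
    rng = np.random.default_rng(7)
    path = _write(tmp_path, _random_chain_text(rng))
    for chain in read_chain(path):
        inv = invert_chain(chain)
        for pos in range(chain.source_span.start, chain.source_span.end, 13):
            img = chain.map_base(pos)
            if img is not None:
                assert inv.map_base(img) == pos


def test_write_read_chain_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    path = _write(tmp_path, _random_chain_text(rng))
    chains = read_chain(path)
    out = tmp_path / "rt.chain"
    write_chain(chains, out)
    assert read_chain(out) == chains
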