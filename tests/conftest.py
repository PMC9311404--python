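import pytest

from sltscan import synthetic_data as sd
from sltscan.formats import AlignedRead
from sltscan.sl_motif import CONSERVED_SL


@pytest.fixture(scope="session")
def sim_factory(tmp_path_factory):
    """Cache of generated synthetic datasets keyed by (seed, overrides)."""
    cache = {}

    def get(seed=1, **overrides):
        key = (seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = sd.SimulationConfig(seed=seed, **overrides)
            out = tmp_path_factory.mktemp(f"sim_s{seed}")
            cache[key] = sd.generate(cfg, out)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def sim(sim_factory):
    return sim_factory(1)


@pytest.fixture(scope="session")
def recovery(sim):
    return sd.end_to_end_check(sim)


def make_read(target="g1", start=1, cigar=((("M", 50)),), seq=None, nm=0,
              proper=True, rev=False, rid="r1"):
    """Construct an AlignedRead; sequence defaults to A-fill of the right
    length, with the conserved SL 12-mer insertable via seq."""
    cigar = [tuple(c) for c in cigar]
    if seq is None:
        seq = "A" * sum(n for op, n in cigar if op in "MIS")
    return AlignedRead(read_id=rid, target_id=target, start=start,
                       cigar=cigar, sequence=seq, properly_paired=proper,
                       edit_distance=nm, is_reverse=rev)


def sl_read(target, site, n_clip=12, aligned=130, rid="r", pad="T"):
    """A read whose 5' soft clip ends with the conserved SL region, placing
    the SL addition site at reference position ``site``."""
    clip_seq = pad * (n_clip - 12) + CONSERVED_SL
    seq = clip_seq + "A" * aligned
    return make_read(target=target, start=site,
                     cigar=[("S", n_clip), ("M", aligned)], seq=seq, rid=rid)
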