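import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from synphylo.simulate import SimulationConfig, simulate_group_set


@pytest.fixture(scope="session")
def small_group_set():
    """Six simulated groups at modest length, shared across read-only tests."""
    cfg = SimulationConfig(n_groups=6, seq_len_codons=150, seed=42)
    return simulate_group_set(cfg)


@pytest.fixture()
def group_table_text():
    """A well-formed group table with 3 groups (3/4/2 cotton paralogs)."""
    rows = ["group_id\tspecies\tgene_id"]
    for gid, n_cotton in [("g1", 3), ("g2", 4), ("g3", 2)]:
        rows.append(f"{gid}\tVv\tVv_{gid}")
        rows.append(f"{gid}\tTc\tTc_{gid}")
        for j in range(1, n_cotton + 1):
            rows.append(f"{gid}\tGr\tGr_{gid}_{j}")
    return "\n".join(rows) + "\n"
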