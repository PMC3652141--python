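import numpy as np
import pytest

from nitroscreen import builtin_table1, builtin_table3, parse_smiles
from nitroscreen.chem_io import LOMUSTINE_SMILES, DescriptorRecord, DescriptorTable


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def table3():
    return builtin_table3()


@pytest.fixture(scope="session")
def lomustine():
    return parse_smiles(LOMUSTINE_SMILES, "lomustine")


def make_random_table(rng: np.random.Generator, n: int, with_volume: bool = True) -> DescriptorTable:
    """Random continuous descriptor table for property/oracle tests."""
    records = []
    for i in range(n):
        records.append(
            DescriptorRecord(
                agent_id=f"R{i + 1}",
                log_p=float(rng.normal(2.5, 1.0)),
                psa=float(rng.uniform(20, 120)),
                n_atoms=int(rng.integers(8, 30)),
                fw=float(rng.uniform(150, 450)),
                n_on=int(rng.integers(2, 9)),
                n_ohnh=int(rng.integers(0, 4)),
                n_ro5_violations=0,
                n_rot=int(rng.integers(0, 10)),
                volume=float(rng.uniform(120, 400)) if with_volume else None,
            )
        )
    return DescriptorTable(records, provenance="synthetic")
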