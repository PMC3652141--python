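"""Synthetic nitrosourea libraries for end-to-end pipeline testing.

Two generators:

* :func:`enumerate_analogs` builds real structures by attaching R-group
  fragments to the fixed nitrosourea warhead O=C(NHR)N(N=O)CH2CH2Cl
  (the cyclohexyl fragment reproduces lomustine), so the descriptor and
  screening stages can be exercised on chemistry rather than tables.

* :func:`simulate_descriptor_table` emulates the statistical structure of
  the 18-agent reference table without touching the chemistry stack:
  Log P ~ Normal(2.524, 0.5337) truncated to [1.0, 4.5]; PSA pinned at
  61.77 Å² except for a hydroxylated subpopulation at 82.0 Å² (which also
  carries one extra acceptor and donor, the signature of agent 12);
  heavy atoms uniform on 12..17, rotatable bonds uniform on 4..8, and
  formula weight regenerated from the linear FW model plus Gaussian noise
  truncated to the requested range.

Both are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats

from .chem_io import DescriptorRecord, DescriptorTable, Molecule
from .errors import InputError, StructureError
from .screening import rule_of_five_violations

#: Nitrosourea core with the R attachment as a labeled dummy atom.
CORE_SMILES = "[*:1]NC(=O)N(N=O)CCCl"

#: Default R-group fragment library: (SMILES with one [*:1] dummy, category).
DEFAULT_FRAGMENTS: tuple[tuple[str, str], ...] = (
    ("[*:1]C1CCCCC1", "cycloalkyl"),      # cyclohexyl -> lomustine
    ("[*:1]C1CCCC1", "cycloalkyl"),
    ("[*:1]C1CCC1", "cycloalkyl"),
    ("[*:1]C1CCCCCC1", "cycloalkyl"),
    ("[*:1]C", "alkyl"),
    ("[*:1]CC", "alkyl"),
    ("[*:1]CCC", "alkyl"),
    ("[*:1]C(C)C", "alkyl"),
    ("[*:1]CCCC", "alkyl"),
    ("[*:1]C(C)CC", "alkyl"),
    ("[*:1]CC(C)C", "alkyl"),
    ("[*:1]CC=C", "alkenyl"),
    ("[*:1]CCC=C", "alkenyl"),
    ("[*:1]C/C=C/C", "alkenyl"),
    ("[*:1]CC=C(C)C", "alkenyl"),
    ("[*:1]CCCl", "halogenated"),
    ("[*:1]CCBr", "halogenated"),
    ("[*:1]C1CCC(Cl)CC1", "halogenated"),
    ("[*:1]C1CCC(Br)CC1", "halogenated"),
    ("[*:1]CCO", "hydroxyalkyl"),
    ("[*:1]C(C)CO", "hydroxyalkyl"),
    ("[*:1]CC(C)O", "hydroxyalkyl"),
    ("[*:1]C1CC1", "ring"),
    ("[*:1]C1CCC(C)CC1", "ring"),
    ("[*:1]CC(C)=S", "thio"),
)


@dataclasses.dataclass(frozen=True)
class SubstituentLibrary:
    """R-group fragments with category tags; one attachment point each."""

    fragments: tuple[tuple[str, str], ...] = DEFAULT_FRAGMENTS

    def __post_init__(self) -> None:
        for smi, _ in self.fragments:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise StructureError(f"invalid fragment SMILES: {smi!r}")
            n_dummy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
            if n_dummy != 1:
                raise StructureError(
                    f"fragment {smi!r} has {n_dummy} attachment points, need exactly 1"
                )

    def __len__(self) -> int:
        return len(self.fragments)


def _attach(fragment_smiles: str) -> Chem.Mol:
    core = Chem.MolFromSmiles(CORE_SMILES)
    frag = Chem.MolFromSmiles(fragment_smiles)
    combined = Chem.molzip(Chem.CombineMols(core, frag))
    Chem.SanitizeMol(combined)
    return combined


def enumerate_analogs(
    lib: SubstituentLibrary,
    n: int,
    seed: int,
    replace: bool = False,
) -> list[Molecule]:
    """Sample ``n`` R-groups from ``lib`` and attach them to the core.

    Without replacement, ``n`` must not exceed the library size.
    Deterministic for a fixed seed.
    """
    if not replace and n > len(lib):
        raise InputError(
            f"requested {n} distinct analogs but library has {len(lib)} fragments "
            "(pass replace=True to sample with replacement)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), size=n, replace=replace)
    out = []
    for k, i in enumerate(idx, start=1):
        smi, category = lib.fragments[int(i)]
        mol = _attach(smi)
        out.append(
            Molecule(
                identifier=f"A{k}:{category}",
                smiles=Chem.MolToSmiles(mol),
                mol=mol,
            )
        )
    return out


@dataclasses.dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the descriptor-table simulator (reference-set defaults)."""

    n_compounds: int = 18
    seed: int = 0
    logp_mean: float = 2.524
    logp_sd: float = 0.5337
    logp_bounds: tuple[float, float] = (1.0, 4.5)
    fw_range: tuple[float, float] = (190.0, 315.0)
    fw_noise_sd: float = 14.0
    hydroxylated_fraction: float = 1.0 / 18.0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise InputError("n_compounds must be >= 1")
        if self.logp_sd <= 0 or self.fw_noise_sd <= 0:
            raise InputError("standard deviations must be positive")
        if not 0 <= self.hydroxylated_fraction <= 1:
            raise InputError("hydroxylated_fraction must be in [0, 1]")


# FW linear model used to regenerate formula weight in pure-table mode.
_FW_COEFS = {"intercept": -24.859, "log_p": 0.9578, "psa": -0.04598,
             "n_atoms": 19.236, "n_rot": -3.947}


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_descriptor_table(p: SyntheticParams) -> DescriptorTable:
    """Simulate a descriptor table with the reference set's structure.

    The number of hydroxylated (agent-12-like) records is
    round(fraction * n), placed at random positions, so the default
    fraction of 1/18 yields exactly one such record at n = 18.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_compounds
    log_p = _truncnorm(rng, p.logp_mean, p.logp_sd, *p.logp_bounds, size=n)
    n_hydroxy = int(round(p.hydroxylated_fraction * n))
    hydroxy = np.zeros(n, dtype=bool)
    if n_hydroxy:
        hydroxy[rng.choice(n, size=min(n_hydroxy, n), replace=False)] = True
    psa = np.where(hydroxy, 82.0, 61.77)
    n_on = np.where(hydroxy, 6, 5)
    n_ohnh = np.where(hydroxy, 2, 1)
    n_atoms = rng.integers(12, 18, size=n)  # 12..17 inclusive
    n_rot = rng.integers(4, 9, size=n)      # 4..8 inclusive
    lin = (
        _FW_COEFS["intercept"]
        + _FW_COEFS["log_p"] * log_p
        + _FW_COEFS["psa"] * psa
        + _FW_COEFS["n_atoms"] * n_atoms
        + _FW_COEFS["n_rot"] * n_rot
    )
    lo, hi = p.fw_range
    noise = np.array(
        [_truncnorm(rng, 0.0, p.fw_noise_sd, lo - l, hi - l, size=1)[0] for l in lin]
    )
    fw = lin + noise
    records = []
    for i in range(n):
        rec = DescriptorRecord(
            agent_id=f"S{i + 1}",
            log_p=float(log_p[i]),
            psa=float(psa[i]),
            n_atoms=int(n_atoms[i]),
            fw=float(fw[i]),
            n_on=int(n_on[i]),
            n_ohnh=int(n_ohnh[i]),
            n_ro5_violations=0,
            n_rot=int(n_rot[i]),
            volume=None,
        )
        v = rule_of_five_violations(rec)
        if v:
            rec = dataclasses.replace(rec, n_ro5_violations=v)
        records.append(rec)
    return DescriptorTable(records, provenance="synthetic")


def screening_fixture(n_total: int, n_pass: int, seed: int) -> DescriptorTable:
    """A library with exactly ``n_pass`` compounds passing the full screen.

    Passing records satisfy CNS-A, CNS-B and have zero Rule-of-5
    violations (by the simulator's construction); each failing record
    violates at least one criterion of that conjunction (overweight,
    overly lipophilic, too polar, or too many donors).
    """
    if n_pass > n_total:
        raise InputError(f"n_pass ({n_pass}) exceeds n_total ({n_total})")
    rng = np.random.default_rng(seed)
    passers = simulate_descriptor_table(
        SyntheticParams(n_compounds=max(n_pass, 1), seed=int(rng.integers(2**31)))
    ).records[:n_pass]

    n_fail = n_total - n_pass
    fail_records = []
    modes = rng.integers(0, 4, size=n_fail)
    base = simulate_descriptor_table(
        SyntheticParams(n_compounds=max(n_fail, 1), seed=int(rng.integers(2**31)))
    ).records[:n_fail]
    for i, (mode, rec) in enumerate(zip(modes, base)):
        if mode == 0:  # too heavy: fails FW <= 400 and FW <= 450
            rec = dataclasses.replace(rec, fw=float(rng.uniform(460, 620)))
        elif mode == 1:  # too lipophilic: fails Log P <= 5
            rec = dataclasses.replace(rec, log_p=float(rng.uniform(5.2, 7.5)))
        elif mode == 2:  # too polar: fails PSA <= 90
            rec = dataclasses.replace(rec, psa=float(rng.uniform(95, 140)))
        else:  # too many donors: fails donors <= 3
            rec = dataclasses.replace(rec, n_ohnh=int(rng.integers(4, 7)))
        rec = dataclasses.replace(
            rec, n_ro5_violations=rule_of_five_violations(rec)
        )
        fail_records.append(rec)

    records = list(passers) + fail_records
    order = rng.permutation(len(records))
    records = [
        dataclasses.replace(records[j], agent_id=f"L{i + 1}")
        for i, j in enumerate(order)
    ]
    return DescriptorTable(records, provenance="synthetic")
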