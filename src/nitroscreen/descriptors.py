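"""Molecular descriptors for CNS screening, computed from structures.

All descriptors are delegated to RDKit's published implementations:

* formula weight — IUPAC standard atomic weights incl. implicit H;
* TPSA — Ertl's fragment-contribution topological polar surface area
  (N/O contributions only), Å²;
* H-bond donors/acceptors — Lipinski convention: donors are hydrogens on
  N or O (an -OH and an -NH2 contribute 1 and 2 respectively), acceptors
  are the N plus O atom count;
* rotatable bonds — acyclic single bonds between two non-terminal heavy
  atoms, excluding amide C-N (RDKit default pattern);
* Log P — Crippen atom-contribution estimate. The 18-agent reference
  values come from a different (proprietary) calculator; the Crippen
  estimate is an open substitute that agrees with them to within about
  one log unit, so reference statistics always use tabulated Log P.

Molecular volume has no open counterpart of the reference 3D-fitted group
contribution method, so it is pluggable: pass ``volume_method`` to
:func:`compute_descriptors` or leave volume absent.
"""

from __future__ import annotations

from typing import Callable, Optional

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem_io import DescriptorRecord, Molecule

__all__ = [
    "formula_weight", "heavy_atom_count", "tpsa", "hbd_count", "hba_count",
    "rotatable_bond_count", "logp_estimate", "compute_descriptors",
]

#: Documented agreement band between the Crippen estimate and the
#: reference (proprietary) Log P values, in log units.
LOGP_TOLERANCE = 1.0


def formula_weight(m: Molecule) -> float:
    """Average molecular weight in daltons, including implicit hydrogens."""
    return Descriptors.MolWt(m.mol)


def heavy_atom_count(m: Molecule) -> int:
    """Number of non-hydrogen atoms."""
    return m.mol.GetNumHeavyAtoms()


def tpsa(m: Molecule) -> float:
    """Ertl topological polar surface area (N/O contributions), Å²."""
    return Descriptors.TPSA(m.mol)


def hbd_count(m: Molecule) -> int:
    """Hydrogen-bond donors: count of hydrogens attached to N or O."""
    return rdMolDescriptors.CalcNumLipinskiHBD(m.mol)


def hba_count(m: Molecule) -> int:
    """Hydrogen-bond acceptors: count of N plus O atoms."""
    return rdMolDescriptors.CalcNumLipinskiHBA(m.mol)


def rotatable_bond_count(m: Molecule) -> int:
    """Acyclic single bonds between non-terminal heavy atoms, amide C-N excluded."""
    return rdMolDescriptors.CalcNumRotatableBonds(m.mol)


def logp_estimate(m: Molecule) -> float:
    """Crippen atom-contribution octanol-water Log P (see module note)."""
    return Crippen.MolLogP(m.mol)


def compute_descriptors(
    m: Molecule,
    logp_override: Optional[float] = None,
    volume_method: Optional[Callable[[Molecule], float]] = None,
) -> DescriptorRecord:
    """Assemble the full descriptor record for one molecule.

    ``logp_override`` replaces the Crippen estimate (used when a reference
    Log P is available). ``volume_method``, if given, supplies molecular
    volume in Å³; otherwise volume is absent.
    """
    # imported late: screening depends on chem_io, not on this module
    from .screening import rule_of_five_violations

    log_p = logp_estimate(m) if logp_override is None else float(logp_override)
    partial = DescriptorRecord(
        agent_id=m.identifier or m.smiles,
        log_p=log_p,
        psa=tpsa(m),
        n_atoms=heavy_atom_count(m),
        fw=formula_weight(m),
        n_on=hba_count(m),
        n_ohnh=hbd_count(m),
        n_ro5_violations=0,
        n_rot=rotatable_bond_count(m),
        volume=volume_method(m) if volume_method is not None else None,
    )
    n_viol = rule_of_five_violations(partial)
    if n_viol:
        partial = DescriptorRecord(
            **{**partial.__dict__, "n_ro5_violations": n_viol}
        )
    return partial
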