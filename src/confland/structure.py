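"""Structure superposition, state classification, ranking, and landscapes.

Predicted models are superposed onto experimentally determined active and
inactive references over a configured residue selection (CA atoms by
default, the convention for transmembrane-segment comparisons), classified
into conformational states by segment RMSD under one of three rules, ranked
by predictor confidence (mean plDDT or complex ipTM), and summarized into
state-population tables.

Classification rules
--------------------
``argmin_excl3``
    The state is the reference with the lower RMSD; models farther than
    3.0 Angstrom from *both* references are excluded from analysis.
``thresh35``
    A state is called only when its RMSD is strictly below 3.5 Angstrom
    (and not above the other state's); otherwise the model is excluded.
    Suited to reference pairs separated by large RMSD.
``gcgr54``
    The state is the argmin if the lower RMSD does not exceed 5.4 Angstrom
    — the separation of the reference segments themselves — and the mean
    plDDT exceeds 70; otherwise excluded.

Exact RMSD ties under an argmin rule yield ``ambiguous`` rather than an
arbitrary assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .errors import ArgumentError, FormatError, SelectionError

#: Exclusion radius for the argmin rule: models farther than this from both
#: references are dropped from landscape statistics.
RMSD_EXCLUSION = 3.0
#: Strict per-state acceptance threshold for well-separated reference pairs.
RMSD_STRICT_CALL = 3.5
#: Reference-segment separation used as the acceptance radius for receptor
#: landscapes, gated on mean plDDT > 70.
RMSD_REFERENCE_GAP = 5.4
PLDDT_GATE = 70.0

STATES = ("active", "inactive", "ambiguous", "excluded")
RULES = ("argmin_excl3", "thresh35", "gcgr54")

BACKBONE_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# structure containers and PDB I/O


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    resseq: int
    name: str
    atoms: tuple[AtomRecord, ...]
    plddt: float = 0.0


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        seqs = [r.resseq for r in self.residues]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise FormatError(
                f"chain {self.chain_id}: residue numbers must strictly increase"
            )


@dataclass(frozen=True)
class StructureModel:
    """Atomic coordinates with per-residue plDDT, one entry per chain."""

    chains: tuple[Chain, ...]
    model_id: str = "model"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise SelectionError(f"no chain {chain_id!r} in model {self.model_id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def mean_plddt(self) -> float:
        vals = [r.plddt for c in self.chains for r in c.residues]
        return float(np.mean(vals))


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file; B-factors are read as per-residue plDDT.

    Only the first MODEL is used; for disordered atoms the altloc with the
    highest occupancy (ties broken alphabetically) is kept; HETATM records
    are ignored.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"{path}: no ATOM records")
    chains = []
    for bchain in models[0]:
        residues = []
        for bres in bchain:
            if bres.id[0] != " ":
                continue
            atoms = []
            bfactors = []
            for batom in bres:
                if batom.is_disordered():
                    children = sorted(
                        batom.disordered_get_list(),
                        key=lambda a: (-a.get_occupancy(), a.get_altloc()),
                    )
                    batom = children[0]
                x, y, z = (float(v) for v in batom.get_coord())
                atoms.append(
                    AtomRecord(batom.get_name(), batom.element or "", (x, y, z))
                )
                bfactors.append(float(batom.get_bfactor()))
            if atoms:
                residues.append(
                    Residue(
                        int(bres.id[1]),
                        bres.get_resname().strip(),
                        tuple(atoms),
                        float(np.mean(bfactors)),
                    )
                )
        if residues:
            chains.append(Chain(bchain.id, tuple(residues)))
    if not chains:
        raise FormatError(f"{path}: no ATOM records")
    return StructureModel(tuple(chains), model_id=Path(path).stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB, storing per-residue plDDT in the B-factor column."""
    sb = StructureBuilder()
    sb.init_structure(model.model_id)
    sb.init_model(0)
    for chain in model.chains:
        sb.init_chain(chain.chain_id)
        sb.init_seg("    ")
        for res in chain.residues:
            sb.init_residue(res.name, " ", res.resseq, " ")
            for atom in res.atoms:
                fullname = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                sb.init_atom(
                    atom.name,
                    np.asarray(atom.xyz, dtype=np.float64),
                    float(res.plddt),
                    1.0,
                    " ",
                    fullname,
                    element=atom.element or None,
                )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# residue selections


@dataclass(frozen=True)
class ResidueSelection:
    """Chain segments plus the atom subset used for superposition.

    ``segments`` are ``(chain_id, start_resseq, end_resseq)`` with inclusive
    ends; segments of one chain may not overlap.
    """

    segments: tuple[tuple[str, int, int], ...]
    atom_subset: Literal["CA", "backbone", "all-heavy"] = "CA"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ArgumentError("selection needs at least one segment")
        if self.atom_subset not in ("CA", "backbone", "all-heavy"):
            raise ArgumentError(f"unknown atom subset {self.atom_subset!r}")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain_id, start, end in self.segments:
            if start > end:
                raise ArgumentError(
                    f"segment {chain_id}:{start}-{end} has start > end"
                )
            for s, e in by_chain.get(chain_id, []):
                if start <= e and s <= end:
                    raise ArgumentError(
                        f"overlapping segments on chain {chain_id}"
                    )
            by_chain.setdefault(chain_id, []).append((start, end))

    def _residue_atoms(self, res: Residue, chain_id: str) -> list[AtomRecord]:
        by_name = {a.name: a for a in res.atoms}
        if self.atom_subset == "CA":
            if "CA" not in by_name:
                raise SelectionError(
                    f"chain {chain_id} residue {res.resseq}: no CA atom"
                )
            return [by_name["CA"]]
        if self.atom_subset == "backbone":
            missing = [n for n in BACKBONE_ATOMS if n not in by_name]
            if missing:
                raise SelectionError(
                    f"chain {chain_id} residue {res.resseq}: "
                    f"missing backbone atoms {missing}"
                )
            return [by_name[n] for n in BACKBONE_ATOMS]
        return [a for a in res.atoms if a.element.upper() != "H"]

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Coordinates (N, 3) of the selected atoms, in segment order."""
        coords = []
        for chain_id, start, end in self.segments:
            chain = model.chain(chain_id)
            by_seq = {r.resseq: r for r in chain.residues}
            for resseq in range(start, end + 1):
                if resseq not in by_seq:
                    raise SelectionError(
                        f"chain {chain_id} residue {resseq} not in model "
                        f"{model.model_id!r}"
                    )
                for atom in self._residue_atoms(by_seq[resseq], chain_id):
                    coords.append(atom.xyz)
        return np.asarray(coords, dtype=np.float64)


# ---------------------------------------------------------------------------
# superposition


def kabsch_rmsd(
    P: np.ndarray, Q: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of P onto Q.

    Returns ``(rmsd, R, t)`` where ``x @ R.T + t`` maps P into Q's frame.
    The rotation is proper: a reflection in the SVD solution is corrected
    via the determinant sign, per the standard Kabsch treatment.
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ArgumentError(f"point sets must both be (N, 3); got {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ArgumentError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    t = qc - R @ pc
    return rmsd, R, t


def superposed_rmsd(
    P: np.ndarray,
    Q: np.ndarray,
    fit_P: np.ndarray | None = None,
    fit_Q: np.ndarray | None = None,
) -> float:
    """RMSD of P vs Q after fitting on ``fit_P``/``fit_Q`` (default: P/Q)."""
    if fit_P is None or fit_Q is None:
        return kabsch_rmsd(P, Q)[0]
    _rmsd, R, t = kabsch_rmsd(fit_P, fit_Q)
    moved = np.asarray(P) @ R.T + t
    diff = moved - np.asarray(Q)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _whole_ca_pairs(
    model: StructureModel, ref: StructureModel, chain_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Matched CA coordinates over residues shared by model and reference."""
    mp, rp = [], []
    for chain_id in chain_ids:
        mres = {r.resseq: r for r in model.chain(chain_id).residues}
        rres = {r.resseq: r for r in ref.chain(chain_id).residues}
        for resseq in sorted(set(mres) & set(rres)):
            ma = {a.name: a for a in mres[resseq].atoms}.get("CA")
            ra = {a.name: a for a in rres[resseq].atoms}.get("CA")
            if ma and ra:
                mp.append(ma.xyz)
                rp.append(ra.xyz)
    return np.asarray(mp, dtype=np.float64), np.asarray(rp, dtype=np.float64)


def rmsd_to_references(
    model: StructureModel,
    ref_active: StructureModel,
    ref_inactive: StructureModel,
    selection: ResidueSelection,
    model_selection: ResidueSelection | None = None,
    fit_on: Literal["selection", "whole"] = "selection",
) -> tuple[float, float]:
    """Segment RMSD of a model to the active and inactive references.

    ``fit_on="selection"`` superposes on the selection itself (default);
    ``fit_on="whole"`` fits on all CA atoms shared with each reference and
    then measures the selection without refitting.
    """
    msel = model_selection or selection
    p = msel.resolve(model)
    out = []
    chain_ids = tuple(dict.fromkeys(seg[0] for seg in msel.segments))
    for ref in (ref_active, ref_inactive):
        q = selection.resolve(ref)
        if p.shape != q.shape:
            raise ArgumentError(
                f"selection resolves to {p.shape[0]} atoms on the model but "
                f"{q.shape[0]} on the reference"
            )
        if fit_on == "whole":
            fp, fq = _whole_ca_pairs(model, ref, chain_ids)
            out.append(superposed_rmsd(p, q, fp, fq))
        else:
            out.append(superposed_rmsd(p, q))
    return out[0], out[1]


def reference_gap_rmsd(
    ref_active: StructureModel,
    ref_inactive: StructureModel,
    selection: ResidueSelection,
    fit_on: Literal["selection", "whole"] = "selection",
) -> float:
    """RMSD between the two references over the selection.

    This is the quantity that motivates the acceptance radius of the
    ``gcgr54`` rule: a model within the references' own separation of one
    of them can be assigned to that state.
    """
    p = selection.resolve(ref_active)
    q = selection.resolve(ref_inactive)
    if fit_on == "whole":
        chain_ids = tuple(dict.fromkeys(seg[0] for seg in selection.segments))
        fp, fq = _whole_ca_pairs(ref_active, ref_inactive, chain_ids)
        return superposed_rmsd(p, q, fp, fq)
    return superposed_rmsd(p, q)


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class StateCall:
    """Per-model conformational-state classification."""

    model_id: str
    rmsd_active: float
    rmsd_inactive: float
    mean_plddt: float
    iptm: float | None
    state: str
    rule: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ArgumentError(f"unknown state {self.state!r}")


def classify_state(
    rmsds: tuple[float, float],
    scores: tuple[float, float | None],
    rule: str,
    model_id: str = "model",
) -> StateCall:
    """Apply one classification rule to a model's reference RMSDs and scores.

    See the module docstring for the three rules. A pure function: identical
    inputs always produce the identical call.
    """
    ra, ri = float(rmsds[0]), float(rmsds[1])
    plddt, iptm = scores
    if rule not in RULES:
        raise ArgumentError(f"unknown rule {rule!r}; expected one of {RULES}")

    def argmin_state() -> str:
        if ra < ri:
            return "active"
        if ri < ra:
            return "inactive"
        return "ambiguous"

    if rule == "argmin_excl3":
        state = "excluded" if min(ra, ri) > RMSD_EXCLUSION else argmin_state()
    elif rule == "thresh35":
        if ra == ri:
            state = "ambiguous" if ra < RMSD_STRICT_CALL else "excluded"
        elif ra < RMSD_STRICT_CALL and ra <= ri:
            state = "active"
        elif ri < RMSD_STRICT_CALL and ri <= ra:
            state = "inactive"
        else:
            state = "excluded"
    else:  # gcgr54
        if min(ra, ri) <= RMSD_REFERENCE_GAP and plddt > PLDDT_GATE:
            state = argmin_state()
        else:
            state = "excluded"
    return StateCall(model_id, ra, ri, float(plddt), iptm, state, rule)


def rank_top_fraction(
    calls: Sequence[StateCall],
    metric: Literal["plddt", "iptm"],
    fraction: float,
) -> list[StateCall]:
    """The ``ceil(fraction * n)`` highest-confidence calls, descending.

    Ties are broken by model id so the ranking is order-invariant.
    """
    if not calls:
        raise ArgumentError("calls must be nonempty")
    if not 0.0 < fraction <= 1.0:
        raise ArgumentError(f"fraction must be in (0, 1], got {fraction}")
    if metric == "plddt":
        key = [c.mean_plddt for c in calls]
    elif metric == "iptm":
        if any(c.iptm is None for c in calls):
            raise ArgumentError("ipTM ranking requested but some calls lack ipTM")
        key = [c.iptm for c in calls]
    else:
        raise ArgumentError(f"unknown metric {metric!r}")
    order = sorted(zip(key, calls), key=lambda kc: (-kc[0], kc[1].model_id))
    k = math.ceil(fraction * len(calls))
    return [c for _v, c in order[:k]]


def landscape_summary(calls: Sequence[StateCall]) -> pd.DataFrame:
    """State counts and percentages over a set of calls.

    Percentages are taken over *all* calls (excluded and ambiguous
    included), so the four state percentages sum to 100.
    """
    if not calls:
        raise ArgumentError("calls must be nonempty")
    counts = {s: sum(1 for c in calls if c.state == s) for s in STATES}
    n = len(calls)
    return pd.DataFrame(
        {
            "count": [counts[s] for s in STATES],
            "percent": [100.0 * counts[s] / n for s in STATES],
        },
        index=pd.Index(STATES, name="state"),
    )


def landscape_table(calls: Sequence[StateCall]) -> pd.DataFrame:
    """One row per model: RMSDs, scores, and the assigned state."""
    return pd.DataFrame(
        {
            "model": [c.model_id for c in calls],
            "rmsd_active": [c.rmsd_active for c in calls],
            "rmsd_inactive": [c.rmsd_inactive for c in calls],
            "plddt": [c.mean_plddt for c in calls],
            "iptm": [c.iptm for c in calls],
            "state": [c.state for c in calls],
        }
    )
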