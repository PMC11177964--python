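"""Synthetic complexes and mutation datasets for end-to-end testing.

Every stage of the pipeline is testable without downloads: a deterministic
toy two-chain "dimer" with idealized helical geometry and controllable
interface contacts stands in for an experimental complex; a perturbation
operator emulates predicted-copy displacement with a per-residue amplitude
profile (the mechanism behind flexibility-vs-error analyses); and a
mutation-dataset generator produces feature matrices whose ΔΔG is a known
linear function of named features plus Gaussian noise, enabling
parameter-recovery tests of the regression stage.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import Atom, MutationSpec, Structure, write_structure

__all__ = [
    "ToyDimerConfig",
    "SyntheticDataset",
    "make_toy_dimer",
    "perturb_structure",
    "random_rigid_motion",
    "synth_mutation_dataset",
    "write_fixture_set",
]

CONTACT_CUTOFF = 5.0
_SEQ_CYCLE = "AVLSTNQEDK"  # CB-bearing residues only; atoms are backbone+CB

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)


@dataclass(frozen=True)
class ToyDimerConfig:
    """Parameters of the synthetic two-chain complex."""

    residues_per_chain: int = 30
    interface_contacts: int = 6
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_chain < 3:
            raise ValueError("need at least 3 residues per chain")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.interface_contacts <= self.residues_per_chain:
            raise ValueError("infeasible interface contact count")


def _helix_residue(i: int, axis_x: float, phase: float) -> dict[str, np.ndarray]:
    """Idealized backbone + CB positions for residue i of a helix along z."""
    theta = i * _HELIX_TURN + phase
    z = i * _HELIX_RISE

    def ring(dtheta: float, dz: float, radius: float) -> np.ndarray:
        t = theta + dtheta
        return np.array([axis_x + radius * np.cos(t), radius * np.sin(t), z + dz])

    ca = ring(0.0, 0.0, _HELIX_RADIUS)
    cb_dir = ca - np.array([axis_x, 0.0, z])
    cb = ca + 1.53 * cb_dir / np.linalg.norm(cb_dir)
    return {
        "N": ring(-0.45, -0.75, 1.65),
        "CA": ca,
        "C": ring(0.45, 0.75, 1.65),
        "O": ring(0.55, 0.85, 2.85),
        "CB": cb,
    }

_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _chain_atoms(
    chain: str,
    n_res: int,
    axis_x_per_res: np.ndarray,
    phase: float,
    seq_offset: int,
    rng: np.random.Generator,
    noise_sigma: float,
) -> list[Atom]:
    from .structure_io import AA1_TO_3

    atoms = []
    mid = (n_res - 1) / 2.0
    for i in range(n_res):
        res_name = AA1_TO_3[_SEQ_CYCLE[(i + seq_offset) % len(_SEQ_CYCLE)]]
        b = 10.0 + 30.0 * ((i - mid) / max(mid, 1.0)) ** 2
        positions = _helix_residue(i, float(axis_x_per_res[i]), phase)
        for name, pos in positions.items():
            coords = pos + rng.normal(0.0, noise_sigma, 3) if noise_sigma > 0 else pos
            atoms.append(
                Atom(
                    element=_ATOM_ELEMENTS[name],
                    coords=coords,
                    chain=chain,
                    res_seq=str(i + 1),
                    res_name=res_name,
                    name=name,
                    b_factor=b,
                )
            )
    return atoms


def _contact_count(structure: Structure) -> int:
    """Chain-B residues with any cross-chain atom within the cutoff."""
    a_coords = np.array([a.coords for a in structure.atoms if a.chain == "A"])
    count = 0
    for key, atoms in structure.residues().items():
        if key[0] != "B":
            continue
        d = np.linalg.norm(
            a_coords[None, :, :] - np.array([a.coords for a in atoms])[:, None, :],
            axis=2,
        )
        if d.min() < CONTACT_CUTOFF:
            count += 1
    return count


def make_toy_dimer(config: ToyDimerConfig) -> Structure:
    """Deterministic two-helix complex with a controlled interface.

    Chain A runs along the z-axis; chain B runs parallel, close for its
    first ``interface_contacts`` residues (each guaranteed a cross-partner
    atom within 5 Å) and veering away beyond them. With zero requested
    contacts the chains are fully separated (minimum cross distance > 5 Å).
    Synthetic B-factors rise quadratically toward the chain termini.
    """
    n = config.residues_per_chain
    rng = np.random.default_rng(config.seed)
    a_axis = np.zeros(n)

    if config.interface_contacts == 0:
        b_axis = np.full(n, 25.0)
        atoms = _chain_atoms("A", n, a_axis, 0.0, 0, rng, config.noise_sigma)
        atoms += _chain_atoms("B", n, b_axis, np.pi, 3, rng, config.noise_sigma)
        st = Structure("TOY", atoms, {"A": "P1", "B": "P2"})
        return st

    window = config.interface_contacts
    for close_x in np.arange(9.5, 4.9, -0.5):
        b_axis = np.array(
            [close_x if i < window else min(close_x + 3.0 * (i - window + 1), 25.0)
             for i in range(n)]
        )
        rng = np.random.default_rng(config.seed)
        atoms = _chain_atoms("A", n, a_axis, 0.0, 0, rng, config.noise_sigma)
        atoms += _chain_atoms("B", n, b_axis, np.pi, 3, rng, config.noise_sigma)
        st = Structure("TOY", atoms, {"A": "P1", "B": "P2"})
        if _contact_count(st) >= window:
            return st
    raise ValueError(
        f"could not realize {window} interface contacts with "
        f"{n} residues per chain"
    )


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=10.0, size=3)


def perturb_structure(
    structure: Structure,
    displacement_profile,
    seed: int = 0,
    rigid_motion: tuple[np.ndarray, np.ndarray] | None = None,
) -> Structure:
    """Displace each residue by a random direction scaled to its profile value.

    ``displacement_profile`` maps (chain, res_seq) to a non-negative
    amplitude in Å, or is a sequence aligned with the structure's residue
    order. An optional rigid motion (rotation, translation) is composed on
    top, emulating an arbitrarily posed predicted copy.
    """
    residues = list(structure.residues().keys())
    if not hasattr(displacement_profile, "get"):
        values = list(displacement_profile)
        if len(values) != len(residues):
            raise ValueError("profile length does not match residue count")
        displacement_profile = dict(zip(residues, values))
    missing = [r for r in residues if r not in displacement_profile]
    if missing:
        raise ValueError(f"profile missing residues: {missing[:3]}...")
    if any(displacement_profile[r] < 0 for r in residues):
        raise ValueError("displacement amplitudes must be non-negative")

    rng = np.random.default_rng(seed)
    offsets = {}
    for key in residues:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offsets[key] = direction * displacement_profile[key]

    atoms = []
    for a in structure.atoms:
        coords = a.coords + offsets[a.residue_key]
        if rigid_motion is not None:
            rot, trans = rigid_motion
            coords = rot @ coords + trans
        atoms.append(Atom(a.element, coords, a.chain, a.res_seq, a.res_name, a.name, a.b_factor))
    return Structure(structure.id + "_pred", atoms, dict(structure.partition))


@dataclass(frozen=True)
class SyntheticDataset:
    """Feature matrix with ΔΔG generated from a known linear effect model."""

    records: pd.DataFrame
    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    noise_sigma: float


def synth_mutation_dataset(
    n: int,
    seed: int = 0,
    n_features: int = 20,
    n_active: int = 5,
    effect_size: float = 1.0,
    noise_sigma: float = 0.3,
    reciprocal: bool = False,
    n_complexes: int = 25,
) -> SyntheticDataset:
    """Mutation records whose ΔΔG is a known function of the features.

    Features are standard normal; the effect model puts weight
    ``effect_size`` on ``n_active`` randomly chosen coordinates, ΔΔG =
    Xβ + ε with ε ~ N(0, noise_sigma²). With ``reciprocal`` the second half
    mirrors the first (negated features and exactly negated ΔΔG), emulating
    forward/reverse mutation pairs; ``pair_id`` links the two halves.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(seed)
    beta = np.zeros(n_features)
    active = rng.choice(n_features, size=n_active, replace=False)
    beta[active] = effect_size

    n_base = n // 2 if reciprocal else n
    X = rng.standard_normal((n_base, n_features))
    y = X @ beta + rng.normal(0.0, noise_sigma, n_base)
    pair_id = np.arange(n_base)
    if reciprocal:
        X = np.vstack([X, -X])
        y = np.concatenate([y, -y])
        pair_id = np.concatenate([pair_id, pair_id])

    wt = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=len(y))
    mut = np.array(
        [rng.choice([a for a in "ARNDCQEGHILKMFPSTWYV" if a != w]) for w in wt]
    )
    records = pd.DataFrame(
        {
            "complex_id": [f"SYN{i % n_complexes:03d}" for i in pair_id],
            "mutation": [
                f"{w}A{pos + 1}{m}" for w, m, pos in zip(wt, mut, pair_id % 180)
            ],
            "pair_id": pair_id,
            "ddg": y,
        }
    )
    return SyntheticDataset(records=records, X=X, y=y, beta=beta, noise_sigma=noise_sigma)


def write_fixture_set(out_dir: str | Path, seed: int = 1) -> pd.DataFrame:
    """Write a small evaluation fixture: reference + displaced "predicted"
    complexes, confidence stubs, and a manifest CSV; returns the manifest."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(3):
        cfg = ToyDimerConfig(residues_per_chain=20, interface_contacts=4, seed=seed + i)
        ref = make_toy_dimer(cfg)
        residues = list(ref.residues().keys())
        scale = 0.02 * (i + 1)
        profile = {
            key: scale * np.mean([a.b_factor for a in atoms])
            for key, atoms in ref.residues().items()
        }
        pred = perturb_structure(
            ref, profile, seed=seed + 100 + i, rigid_motion=random_rigid_motion(rng)
        )
        cid = f"TOY{i}"
        ref_path, pred_path = out / f"{cid}_ref.pdb", out / f"{cid}_pred.pdb"
        conf_path = out / f"{cid}_confidence.json"
        write_structure(ref, ref_path)
        write_structure(pred, pred_path)
        conf_path.write_text(
            json.dumps({"iptm": round(0.9 - 0.15 * i, 3), "ptm": round(0.92 - 0.1 * i, 3)})
        )
        rows.append(
            {
                "complex_id": cid,
                "reference": ref_path.name,
                "predicted": pred_path.name,
                "confidence": conf_path.name,
                "chain_p1": "A",
                "chain_p2": "B",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
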