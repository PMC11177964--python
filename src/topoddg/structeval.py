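"""Predicted-vs-experimental complex evaluation.

Given a predicted complex and its experimental reference, this module maps
chains by sequence, superposes the complexes (least-squares Kabsch fit on
the Cα atoms of all mapped chains jointly), computes the global RMSD and
per-residue backbone RMSD, joins the latter with crystallographic B-factors
(the flexibility proxy), and summarizes batches by RMSD/ipTM/pTM with the
standard confidence bands: ipTM ≥ 0.8 highly confident, ipTM < 0.6 likely
incorrect, pTM ≥ 0.5 globally plausible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .structure_io import AA3_TO_1, Atom, ConfidenceScores, Structure

__all__ = [
    "AlignmentResult",
    "ComplexEvaluation",
    "map_chains",
    "kabsch_superpose",
    "superpose_complexes",
    "per_residue_rmsd",
    "bfactor_rmsd_table",
    "summarize_and_rank",
    "IPTM_HIGH",
    "IPTM_LOW",
    "PTM_GOOD",
    "RMSD_OUTLIER",
]

#: Confidence bands and the RMSD outlier convention used in summaries.
IPTM_HIGH = 0.8
IPTM_LOW = 0.6
PTM_GOOD = 0.5
RMSD_OUTLIER = 4.0

#: Minimum sequence identity for a chain pairing to be accepted.
MIN_CHAIN_IDENTITY = 0.3


@dataclass
class AlignmentResult:
    """A rigid superposition of a predicted complex onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    chain_map: dict[str, str] = field(default_factory=dict)
    per_residue: pd.DataFrame | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ComplexEvaluation:
    """One complex's evaluation row: alignment RMSD plus confidence scores."""

    complex_id: str
    rmsd: float
    iptm: float
    ptm: float
    mean_abs_error: float | None = None

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if not (0 <= self.iptm <= 1 and 0 <= self.ptm <= 1):
            raise ValueError("confidence scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sequences and chain mapping


def _chain_residues(structure: Structure, chain: str) -> list[tuple[str, list[Atom]]]:
    out: dict[str, list[Atom]] = {}
    for a in structure.atoms:
        if a.chain == chain:
            out.setdefault(a.res_seq, []).append(a)
    return list(out.items())


def _chain_sequence(structure: Structure, chain: str) -> str:
    return "".join(
        AA3_TO_1.get(atoms[0].res_name, "X") for _, atoms in _chain_residues(structure, chain)
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity(aligner: Align.PairwiseAligner, s1: str, s2: str) -> float:
    if not s1 or not s2:
        return 0.0
    aln = aligner.align(s1, s2)[0]
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(*aln.aligned)
        for i, j in zip(range(a0, a1), range(b0, b1))
        if s1[i] == s2[j]
    )
    return matches / min(len(s1), len(s2))


def map_chains(predicted: Structure, reference: Structure) -> dict[str, str]:
    """Bijective chain map predicted → reference by sequence identity.

    All bijections are scored when the chain count is small; ties in total
    identity (homodimers) are broken by the lower whole-complex Cα RMSD.
    Reference chains that cannot be matched above 30% identity raise.
    """
    pred_chains = predicted.chains
    ref_chains = reference.chains
    if not pred_chains or not ref_chains:
        raise ValueError("empty structure")
    missing = len(ref_chains) - len(pred_chains)
    if missing > 0:
        raise ValueError(
            f"prediction has {len(pred_chains)} chains but reference has "
            f"{len(ref_chains)}; cannot map {ref_chains[len(pred_chains):]}"
        )
    aligner = _aligner()
    pseqs = {c: _chain_sequence(predicted, c) for c in pred_chains}
    rseqs = {c: _chain_sequence(reference, c) for c in ref_chains}
    ident = {
        (p, r): _identity(aligner, pseqs[p], rseqs[r])
        for p in pred_chains
        for r in ref_chains
    }

    k = len(ref_chains)
    candidates: list[dict[str, str]] = []
    if len(pred_chains) <= 6:
        best_total = -1.0
        for perm in itertools.permutations(pred_chains, k):
            total = sum(ident[(p, r)] for p, r in zip(perm, ref_chains))
            if total > best_total + 1e-9:
                best_total = total
                candidates = [dict(zip(perm, ref_chains))]
            elif abs(total - best_total) <= 1e-9:
                candidates.append(dict(zip(perm, ref_chains)))
    else:  # too many chains to enumerate: optimal assignment on identity
        from scipy.optimize import linear_sum_assignment

        cost = -np.array([[ident[(p, r)] for r in ref_chains] for p in pred_chains])
        rows, cols = linear_sum_assignment(cost)
        candidates = [
            {pred_chains[i]: ref_chains[j] for i, j in zip(rows, cols) if j < k}
        ]

    for cand in candidates:
        bad = [r for p, r in cand.items() if ident[(p, r)] < MIN_CHAIN_IDENTITY]
        if bad:
            listing = {r: {p: round(ident[(p, r)], 3) for p in pred_chains} for r in bad}
            raise ValueError(f"no chain mapping above 30% identity for {listing}")
    if len(candidates) == 1:
        return candidates[0]
    scored = []
    for cand in candidates[:24]:
        res = superpose_complexes(predicted, reference, chain_map=cand)
        scored.append((res.rmsd, sorted(cand.items()), cand))
    scored.sort(key=lambda x: (x[0], x[1]))
    return scored[0][2]


# ---------------------------------------------------------------------------
# Kabsch


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> AlignmentResult:
    """Least-squares optimal rigid superposition of paired coordinate sets.

    Returns the proper rotation R and translation t minimizing
    ‖moving·Rᵀ + t − fixed‖ and the minimized RMSD.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if moving.shape != fixed.shape:
        raise ValueError("paired coordinate sets must have equal shape")
    if moving.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    a, b = moving - cm, fixed - cf
    if np.linalg.matrix_rank(np.vstack([a, b]), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) coordinate sets")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = a @ rot.T + cf
    value = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return AlignmentResult(rotation=rot, translation=cf - cm @ rot.T, rmsd=value)


# ---------------------------------------------------------------------------
# residue pairing and per-residue RMSD


def _paired_residues(
    predicted: Structure, reference: Structure, chain_map: dict[str, str]
) -> list[tuple[str, str, list[Atom], list[Atom]]]:
    """Residue pairs (ref_chain, ref_res_seq, pred_atoms, ref_atoms) via
    per-chain global sequence alignment."""
    aligner = _aligner()
    pairs = []
    for pch, rch in chain_map.items():
        pres = _chain_residues(predicted, pch)
        rres = _chain_residues(reference, rch)
        s1 = "".join(AA3_TO_1.get(a[1][0].res_name, "X") for a in pres)
        s2 = "".join(AA3_TO_1.get(a[1][0].res_name, "X") for a in rres)
        if not s1 or not s2:
            continue
        aln = aligner.align(s1, s2)[0]
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for i, j in zip(range(a0, a1), range(b0, b1)):
                pairs.append((rch, rres[j][0], pres[i][1], rres[j][1]))
    return pairs


def superpose_complexes(
    predicted: Structure,
    reference: Structure,
    chain_map: dict[str, str] | None = None,
    atom_set: str = "CA",
) -> AlignmentResult:
    """Whole-complex superposition over all mapped chains jointly.

    ``atom_set`` selects the alignment atoms: ``"CA"`` (default) or
    ``"backbone"`` (N, CA, C, O common to both).
    """
    if chain_map is None:
        chain_map = map_chains(predicted, reference)
    wanted = {"CA"} if atom_set == "CA" else {"N", "CA", "C", "O"}
    mov, fix = [], []
    for _, _, patoms, ratoms in _paired_residues(predicted, reference, chain_map):
        pd_by = {a.name: a for a in patoms}
        rd_by = {a.name: a for a in ratoms}
        for name in wanted & pd_by.keys() & rd_by.keys():
            mov.append(pd_by[name].coords)
            fix.append(rd_by[name].coords)
    result = kabsch_superpose(np.array(mov), np.array(fix))
    result.chain_map = dict(chain_map)
    return result


def per_residue_rmsd(
    predicted: Structure,
    reference: Structure,
    chain_map: dict[str, str],
    alignment: AlignmentResult,
) -> pd.DataFrame:
    """Backbone RMSD per paired residue after the global superposition.

    Uses the backbone atoms (N, CA, C, O) present in both structures;
    residues with no common backbone atom are skipped and counted in the
    frame's ``attrs["skipped"]``.
    """
    rows = []
    skipped = 0
    for rch, rseq, patoms, ratoms in _paired_residues(predicted, reference, chain_map):
        pd_by = {a.name: a for a in patoms if a.is_backbone}
        rd_by = {a.name: a for a in ratoms if a.is_backbone}
        common = sorted(pd_by.keys() & rd_by.keys())
        if not common:
            skipped += 1
            continue
        moved = alignment.transform(np.array([pd_by[n].coords for n in common]))
        ref = np.array([rd_by[n].coords for n in common])
        value = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
        rows.append(
            {
                "chain": rch,
                "res_seq": rseq,
                "res_name": ratoms[0].res_name,
                "n_atoms": len(common),
                "rmsd": value,
            }
        )
    out = pd.DataFrame(rows, columns=["chain", "res_seq", "res_name", "n_atoms", "rmsd"])
    out.attrs["skipped"] = skipped
    return out


def bfactor_rmsd_table(reference: Structure, per_residue: pd.DataFrame) -> pd.DataFrame:
    """Join per-residue RMSD with mean backbone B-factors of the reference.

    The output (complex, chain, res_seq, b_factor, rmsd, amino-acid type) is
    the table behind flexibility-vs-error analyses; all-zero B-factor
    structures are flagged via ``attrs["zero_bfactors"]``.
    """
    bmap: dict[tuple[str, str], list[float]] = {}
    for a in reference.atoms:
        if a.is_backbone:
            bmap.setdefault((a.chain, a.res_seq), []).append(a.b_factor)
    rows = per_residue.copy()
    rows["b_factor"] = [
        float(np.mean(bmap.get((c, r), [np.nan])))
        for c, r in zip(rows["chain"], rows["res_seq"])
    ]
    rows["aa"] = [AA3_TO_1.get(n, "X") for n in rows["res_name"]]
    rows.insert(0, "complex_id", reference.id)
    rows.attrs["zero_bfactors"] = bool(len(rows) and (rows["b_factor"] <= 0).all())
    return rows


# ---------------------------------------------------------------------------
# batch summaries


def evaluate_complex(
    predicted: Structure,
    reference: Structure,
    confidence: ConfidenceScores,
    mean_abs_error: float | None = None,
) -> tuple[ComplexEvaluation, pd.DataFrame]:
    """Full single-complex evaluation: superpose, then per-residue table."""
    alignment = superpose_complexes(predicted, reference)
    table = per_residue_rmsd(predicted, reference, alignment.chain_map, alignment)
    table = bfactor_rmsd_table(reference, table)
    ev = ComplexEvaluation(
        complex_id=reference.id,
        rmsd=alignment.rmsd,
        iptm=confidence.iptm,
        ptm=confidence.ptm,
        mean_abs_error=mean_abs_error,
    )
    return ev, table


def summarize_and_rank(
    evals: list[ComplexEvaluation],
    top_n: int = 40,
    iptm_high: float = IPTM_HIGH,
    iptm_low: float = IPTM_LOW,
    ptm_good: float = PTM_GOOD,
    rmsd_outlier: float = RMSD_OUTLIER,
) -> dict:
    """Batch summary and worst-complex rankings.

    Returns means of RMSD/ipTM/pTM, the fractions in the standard confidence
    bands, the top-N lists by highest RMSD and by lowest ipTM (ties broken
    lexicographically on complex id), and their intersection — the complexes
    that are poor by both measures.
    """
    if not evals:
        raise ValueError("no evaluations to summarize")
    df = pd.DataFrame(
        [
            {"complex_id": e.complex_id, "rmsd": e.rmsd, "iptm": e.iptm, "ptm": e.ptm}
            for e in evals
        ]
    )
    worst_rmsd = df.sort_values(["rmsd", "complex_id"], ascending=[False, True])
    worst_iptm = df.sort_values(["iptm", "complex_id"], ascending=[True, True])
    top_rmsd = worst_rmsd["complex_id"].head(top_n).tolist()
    top_iptm = worst_iptm["complex_id"].head(top_n).tolist()
    both = sorted(set(top_rmsd) & set(top_iptm))
    return {
        "n": len(df),
        "mean_rmsd": float(df["rmsd"].mean()),
        "mean_iptm": float(df["iptm"].mean()),
        "mean_ptm": float(df["ptm"].mean()),
        "frac_iptm_high": float((df["iptm"] >= iptm_high).mean()),
        "frac_iptm_low": float((df["iptm"] < iptm_low).mean()),
        "frac_ptm_good": float((df["ptm"] >= ptm_good).mean()),
        "frac_rmsd_outlier": float((df["rmsd"] > rmsd_outlier).mean()),
        "top_by_rmsd": top_rmsd,
        "top_by_low_iptm": top_iptm,
        "poor_in_both": both,
    }
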