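"""Synthetic coordinate and topology fixtures.

Coordinate fixtures are idealized A-form geometries built from the
standard base templates: bases of a Watson-Crick pair are related by the
2-fold rotation about the pair x-axis, and successive pairs by the
A-form helical twist (32.7 degrees) and rise (2.81 angstroms).  They are
not energy-minimized and carry no backbone beyond C1', but they place
every hydrogen-bonding and ring atom realistically enough that geometric
pair/stack detection recovers the constructed pairing exactly — the
construction itself is the ground truth.

Topology fixtures are pairing lists with hand-derived expected outcomes,
covering the canonical worked examples: four helices with one
pseudoknotted ("figure2"), the SSU central pseudoknot with its forced
secondary helix, and the A915-U15-U20 base triple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._bases import STANDARD_BASE_COORDS, WC_COMPLEMENT
from .pair_geometry import BasePair
from .structure_io import NucleotideResidue, RnaStructure, write_mmcif

__all__ = [
    "TopologyFixture",
    "make_ideal_duplex",
    "make_bulged_hairpin",
    "make_topology",
    "pairs_from_list",
    "A_FORM_TWIST_DEG",
    "A_FORM_RISE",
]

A_FORM_TWIST_DEG = 32.7
A_FORM_RISE = 2.81


@dataclass
class TopologyFixture:
    """A pairing-list topology with its hand-derived expected outcome."""

    name: str
    n_residues: int
    pairs: list[tuple[int, int, bool]]  # (i, j, canonical)
    expected: dict = field(default_factory=dict)
    labels: dict[str, tuple[int, int]] = field(default_factory=dict)


def pairs_from_list(pairs: list[tuple]) -> list[BasePair]:
    """Build BasePair objects from bare (i, j[, canonical]) tuples.

    Used in pairing-list-only mode where no geometry is available; metric
    fields are filled with idealized values.
    """
    out = []
    for tup in sorted(pairs):
        i, j = tup[0], tup[1]
        canonical = bool(tup[2]) if len(tup) > 2 else True
        out.append(
            BasePair(
                i=i, j=j, edge_i="WC", edge_j="WC",
                orientation="cis", canonical=canonical,
                origin_distance=6.4, plane_angle=0.0,
                vertical_offset=0.0, n_hbonds=2,
            )
        )
    return out


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _base_atoms(
    base: str,
    step: int,
    flipped: bool,
    offset: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Standard-frame base placed at one helical step.

    ``flipped`` applies the Watson-Crick 2-fold (x, -y, -z), producing the
    antiparallel partner strand orientation.
    """
    rot = _rot_z(A_FORM_TWIST_DEG * step)
    shift = np.array([0.0, 0.0, A_FORM_RISE * step])
    if offset is not None:
        shift = shift + offset
    atoms = {}
    for name, (x, y, z) in STANDARD_BASE_COORDS[base].items():
        p = np.array([x, -y, -z]) if flipped else np.array([x, y, z])
        atoms[name] = rot @ p + shift
    return atoms


def _residue(chain: str, seq_index: int, base: str, atoms: dict) -> NucleotideResidue:
    return NucleotideResidue(
        chain_id=chain,
        seq_index=seq_index,
        auth_number=seq_index,
        base_code=base,
        parent=base,
        atoms=atoms,
        complete_base=True,
    )


def _write_with_sidecar(structure: RnaStructure, pairs: list[tuple[int, int]], path: Path) -> None:
    write_mmcif(structure, path, title=path.stem)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"n_residues": structure.n_residues, "pairs": [list(p) for p in pairs]},
                   indent=1) + "\n",
        encoding="utf-8",
    )


def make_ideal_duplex(
    sequence: str,
    path: str | Path | None = None,
) -> tuple[RnaStructure, list[tuple[int, int]]]:
    """Idealized A-form duplex of `sequence` and its Watson-Crick complement.

    Chain A carries ``sequence`` 5'->3'; chain B the antiparallel
    complement.  Residue k of chain A pairs global index 2n+1-k.  When
    ``path`` is given, a deterministic mmCIF file plus a JSON ground-truth
    sidecar are written.
    """
    seq = sequence.strip().upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(seq)
    chain_a = [
        _residue("A", k + 1, seq[k], _base_atoms(seq[k], step=k, flipped=False))
        for k in range(n)
    ]
    chain_b = []
    for m in range(1, n + 1):  # B strand 5'->3'; residue m sits at step n-m
        base = WC_COMPLEMENT[seq[n - m]]
        chain_b.append(_residue("B", m, base, _base_atoms(base, step=n - m, flipped=True)))
    structure = RnaStructure(chains=[("A", chain_a), ("B", chain_b)], source="make_ideal_duplex")
    truth = [(k, 2 * n + 1 - k) for k in range(1, n + 1)]
    if path is not None:
        _write_with_sidecar(structure, truth, Path(path))
    return structure, truth


def make_bulged_hairpin(
    stem_len: int,
    bulge_len: int,
    loop_len: int,
    path: str | Path | None = None,
) -> tuple[RnaStructure, list[tuple[int, int]], list[tuple[int, int]]]:
    """Single-chain hairpin with a bulge inserted mid-stem.

    The stem keeps ideal A-form continuity across the bulge (the bulged
    nucleotides are flipped out, far from the helix), so the flanking
    stacks bridge the defect and the whole stem reads as one helix.

    Returns (structure, ground-truth pairs, bridging stack contacts) —
    the last being the intra-strand stacks that span the bulge junction;
    removing them from a stacking list breaks the stem in two.
    """
    if stem_len < 2:
        raise ValueError("stem_len must be >= 2")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (a hairpin loop needs 3 nt)")
    if bulge_len < 0:
        raise ValueError("bulge_len must be >= 0")
    half = stem_len // 2
    stem5 = ("GC" * stem_len)[:stem_len]
    residues: list[NucleotideResidue] = []

    def add(base: str, atoms: dict) -> int:
        residues.append(_residue("A", len(residues) + 1, base, atoms))
        return len(residues)

    idx5 = []
    for t in range(stem_len):
        if t == half:
            for b in range(bulge_len):  # flipped-out bulge, far off-axis
                off = np.array([25.0 + 10.0 * b, 0.0, A_FORM_RISE * (t - 0.5)])
                add("A", _base_atoms("A", step=0, flipped=False, offset=off))
        idx5.append(add(stem5[t], _base_atoms(stem5[t], step=t, flipped=False)))
    for m in range(loop_len):  # loop spread far from the stem
        off = np.array([-25.0 - 10.0 * m, 0.0, A_FORM_RISE * stem_len])
        add("U", _base_atoms("U", step=0, flipped=False, offset=off))
    idx3 = []
    for t in range(stem_len - 1, -1, -1):  # 3' strand, 5'->3'
        base = WC_COMPLEMENT[stem5[t]]
        idx3.append(add(base, _base_atoms(base, step=t, flipped=True)))
    structure = RnaStructure(chains=[("A", residues)], source="make_bulged_hairpin")
    truth = sorted(zip(idx5, reversed(idx3)))
    bridge: list[tuple[int, int]] = []
    if bulge_len > 0 and half >= 1 and half < stem_len:
        i_before, i_after = idx5[half - 1], idx5[half]
        bridge.append((min(i_before, i_after), max(i_before, i_after)))
        j_after = truth[half - 1][1]   # 3' partner of pair half-1
        j_before = truth[half][1]      # 3' partner of pair half
        bridge.append((min(j_before, j_after), max(j_before, j_after)))
    if path is not None:
        _write_with_sidecar(structure, truth, Path(path))
    return structure, truth, bridge


def _figure2() -> TopologyFixture:
    red = [(k, 61 - k, True) for k in range(1, 6)]
    yellow = [(k, 40 - k, True) for k in range(10, 13)]
    green = [(k, 85 - k, True) for k in range(35, 38)]
    blue = [(k, 120 - k, False) for k in range(40, 43)]
    return TopologyFixture(
        name="figure2",
        n_residues=100,
        pairs=sorted(red + yellow + green + blue),
        expected={
            "helix_count": 4,
            "layer0_count": 3,
            "nonnested_count": 1,
            "nonnested_strand5_start": 40,  # the "blue" analog
        },
    )


def _central_pseudoknot() -> TopologyFixture:
    helix1 = [(k, 34 - k, True) for k in range(9, 14)]       # 5 pairs
    helix2 = [(k, 935 - k, True) for k in range(17, 20)]     # 3 pairs, "Helix 2"
    return TopologyFixture(
        name="central_pseudoknot",
        n_residues=920,
        pairs=sorted(helix1 + helix2),
        expected={
            "helix_count": 2,
            "unforced_layer0_weight": 5,
            "forced_label": "Helix 2",
        },
        labels={"Helix 2": (17, 19)},
    )


def _triple_a915() -> TopologyFixture:
    # The A915-U15-U20 base triple: U15 is the two-partner hub, paired with
    # A915 inside a short helix and with U20 as a lone tertiary pair.
    helix = [(14, 916, True), (15, 915, True), (16, 914, False)]
    lone = [(15, 20, False)]
    return TopologyFixture(
        name="triple_a915",
        n_residues=920,
        pairs=sorted(helix + lone),
        expected={
            "partners_15": [915, 20],
            "partners_20": [15],
            "partners_915": [15],
            "demoted": [(15, 20)],
            "helix_count": 1,
        },
    )


def _random_topology(n_helices: int, seed: int, n_residues: int | None = None) -> TopologyFixture:
    rng = np.random.default_rng(seed)
    n_res = n_residues or max(60, 30 * n_helices)
    used: set[int] = set()
    pairs: list[tuple[int, int, bool]] = []
    made = 0
    attempts = 0
    while made < n_helices and attempts < 2000:
        attempts += 1
        length = int(rng.integers(1, 5))
        s = int(rng.integers(1, n_res - 2 * length))
        e = int(rng.integers(s + 2 * length, n_res + 1))
        seg5 = set(range(s, s + length))
        seg3 = set(range(e - length + 1, e + 1))
        if (seg5 | seg3) & used or max(seg5) >= min(seg3):
            continue
        used |= seg5 | seg3
        pairs.extend((s + k, e - k, True) for k in range(length))
        made += 1
    return TopologyFixture(
        name=f"random-{seed}",
        n_residues=n_res,
        pairs=sorted(pairs),
        expected={"n_helices": made},
    )


def make_topology(
    name: str,
    n_helices: int | None = None,
    seed: int | None = None,
) -> TopologyFixture:
    """Return a named pairing-list topology fixture.

    ``figure2``, ``central_pseudoknot`` and ``triple_a915`` are the worked
    examples with recorded expectations; ``random`` (requires
    ``n_helices`` and ``seed``) generates interleaved helix sets for
    oracle tests, deterministically for a given seed.
    """
    if name == "figure2":
        return _figure2()
    if name == "central_pseudoknot":
        return _central_pseudoknot()
    if name == "triple_a915":
        return _triple_a915()
    if name == "random":
        if n_helices is None or seed is None:
            raise ValueError("random topology requires n_helices and seed")
        return _random_topology(n_helices, seed)
    raise ValueError(f"unknown topology fixture {name!r}")
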