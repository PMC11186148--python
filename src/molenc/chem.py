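"""Self-contained chemistry engine for desk-scale corpora.

Valence-correct random molecular graphs, a SMILES writer/parser for the
subset the generator emits (heavy atoms C/N/O/S/F/Cl/Br, single and double
bonds, branches, ring closures 1-9), uniform-random enumeration of
alternative spellings, and structure-determined synthetic labels.

Hydrogens are implicit throughout.  Aromatic perception, charges, isotopes
and stereochemistry are out of scope for the generator; real-world corpora
with those features still tokenize (see :mod:`molenc.tokenizer`) and may be
canonicalized/enumerated by an external chemistry toolkit behind the same
contracts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "VALENCE",
    "ATOMIC_MASS",
    "MolGraph",
    "SpellingSpec",
    "SmilesError",
    "random_molecule",
    "write_smiles",
    "parse_smiles",
    "canonical_smiles",
    "enumerate_smiles",
    "synthetic_labels",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
]

#: Maximum total bond order per heavy atom (implicit hydrogens fill the rest).
VALENCE: Dict[str, int] = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}

#: Standard atomic masses, used for molecular-weight metadata.
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "F": 18.998, "Cl": 35.45, "Br": 79.904, "H": 1.008,
}

# Element sampling weights for the generator: carbon-dominated organics with
# a realistic sprinkling of heteroatoms and halogens.
_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br")
_ELEMENT_WEIGHTS = np.array([0.70, 0.10, 0.12, 0.03, 0.03, 0.015, 0.005])

_DOUBLE_BOND_PROB = 0.15


class SmilesError(ValueError):
    """Raised for malformed or unsupported SMILES input."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class MolGraph:
    """Implicit-hydrogen molecular graph.

    atoms: element symbol per heavy atom, 0-based indices.
    bonds: (i, j, order) with i < j, order in {1, 2}; connected, simple.
    """

    atoms: Tuple[str, ...]
    bonds: Tuple[Tuple[int, int, int], ...]

    def __post_init__(self):
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> List[List[Tuple[int, int]]]:
        """Neighbor lists: adj[i] = [(j, order), ...] in bond order."""
        adj: List[List[Tuple[int, int]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def valence_used(self) -> List[int]:
        used = [0] * self.n_atoms
        for i, j, order in self.bonds:
            used[i] += order
            used[j] += order
        return used

    def validate(self) -> None:
        """Audit every structural invariant; raise ValueError on violation."""
        n = len(self.atoms)
        if n < 1:
            raise ValueError("graph must have at least one atom")
        for sym in self.atoms:
            if sym not in VALENCE:
                raise ValueError(f"unsupported element {sym!r}")
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range")
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if order not in (1, 2):
                raise ValueError(f"unsupported bond order {order}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        for idx, used in enumerate(self.valence_used()):
            cap = VALENCE[self.atoms[idx]]
            if used > cap:
                raise ValueError(
                    f"valence violation on atom {idx} ({self.atoms[idx]}): "
                    f"{used} > {cap}"
                )
        if n > 1:
            # connectivity via union-find
            parent = list(range(n))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j, _ in self.bonds:
                parent[find(i)] = find(j)
            if len({find(i) for i in range(n)}) != 1:
                raise ValueError("graph is not connected")

    def molecular_weight(self) -> float:
        """Heavy atoms plus implicit hydrogens filling free valence."""
        used = self.valence_used()
        mw = 0.0
        for idx, sym in enumerate(self.atoms):
            mw += ATOMIC_MASS[sym]
            mw += ATOMIC_MASS["H"] * (VALENCE[sym] - used[idx])
        return mw


@dataclass
class SpellingSpec:
    """One concrete way to spell a graph: traversal root and neighbor order.

    neighbor_order maps atom index -> permutation of that atom's neighbor
    indices; atoms absent from the map use ascending neighbor index.
    """

    root: int = 0
    neighbor_order: Dict[int, List[int]] = field(default_factory=dict)

    def order_for(self, atom: int, neighbors: Sequence[int]) -> List[int]:
        if atom not in self.neighbor_order:
            return sorted(neighbors)
        perm = self.neighbor_order[atom]
        if sorted(perm) != sorted(neighbors):
            raise ValueError(
                f"neighbor_order for atom {atom} does not cover its neighbors"
            )
        return list(perm)

    def validate_for(self, g: MolGraph) -> None:
        if not (0 <= self.root < g.n_atoms):
            raise ValueError(f"root {self.root} out of range")
        adj = g.adjacency()
        for atom, perm in self.neighbor_order.items():
            if sorted(perm) != sorted(j for j, _ in adj[atom]):
                raise ValueError(
                    f"neighbor_order for atom {atom} does not cover its neighbors"
                )


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def random_molecule(n_atoms: int, ring_prob: float = 0.3, rng_seed=0) -> MolGraph:
    """Grow a random valence-correct molecule with drug-like statistics.

    A spanning tree is grown atom by atom; growth extends the most recent
    atom with probability 0.5 (favoring chains over star-like branching),
    otherwise a uniformly chosen atom with free valence.  Double bonds
    (15% where capacity allows) never share an atom, so cumulated
    double-bond systems do not occur.  Ring closures are then proposed
    between atoms at graph distance >= 4 (ring size >= 5), each accepted
    with probability ``ring_prob``, up to ``min(n_atoms // 6, 3)`` rings.

    Identical seeds give identical graphs.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    if not (0.0 <= ring_prob <= 1.0):
        raise ValueError("ring_prob must be in [0, 1]")
    rng = _as_rng(rng_seed)

    atoms: List[str] = []
    bonds: List[Tuple[int, int, int]] = []
    free: List[int] = []
    in_double: List[bool] = []

    def draw_element(min_valence: int = 0) -> str:
        while True:
            sym = rng.choice(_ELEMENTS, p=_ELEMENT_WEIGHTS / _ELEMENT_WEIGHTS.sum())
            if VALENCE[sym] >= min_valence:
                return str(sym)

    first = draw_element(min_valence=1)
    atoms.append(first)
    free.append(VALENCE[first])
    in_double.append(False)

    for _ in range(n_atoms - 1):
        candidates = [i for i in range(len(atoms)) if free[i] >= 1]
        last = len(atoms) - 1
        if free[last] >= 1 and rng.random() < 0.5:
            anchor = last
        else:
            anchor = int(rng.choice(candidates))
        order = 1
        if (free[anchor] >= 2 and not in_double[anchor]
                and rng.random() < _DOUBLE_BOND_PROB):
            order = 2
        remaining = n_atoms - len(atoms) - 1
        min_val = order
        if remaining > 0 and sum(free) - order == 0:
            # keep at least one open valence so growth can continue
            min_val = order + 1
        sym = draw_element(min_valence=min_val)
        new_idx = len(atoms)
        atoms.append(sym)
        free.append(VALENCE[sym] - order)
        in_double.append(order == 2)
        if order == 2:
            in_double[anchor] = True
        free[anchor] -= order
        bonds.append((anchor, new_idx, order))

    budget = min(n_atoms // 6, 3)
    if ring_prob > 0 and budget > 0:
        adj: Dict[int, List[int]] = {i: [] for i in range(len(atoms))}
        for i, j, _ in bonds:
            adj[i].append(j)
            adj[j].append(i)

        def distance(src: int, dst: int) -> int:
            frontier, dist, seen = [src], 0, {src}
            while frontier:
                if dst in seen:
                    return dist
                dist += 1
                frontier = [n for f in frontier for n in adj[f] if n not in seen]
                seen.update(frontier)
            return dist

        pairs = [
            (i, j)
            for i in range(len(atoms))
            for j in range(i + 1, len(atoms))
        ]
        rng.shuffle(pairs)
        for i, j in pairs:
            if budget == 0:
                break
            if (free[i] >= 1 and free[j] >= 1 and distance(i, j) >= 4
                    and rng.random() < ring_prob):
                bonds.append((i, j, 1))
                adj[i].append(j)
                adj[j].append(i)
                free[i] -= 1
                free[j] -= 1
                budget -= 1

    return MolGraph(tuple(atoms), tuple(sorted((min(i, j), max(i, j), o) for i, j, o in bonds)))


def write_smiles(g: MolGraph, spec: SpellingSpec | None = None) -> str:
    """Emit SMILES by depth-first traversal under a spelling spec.

    Branches other than the last child are parenthesized; ring-closing back
    edges get paired digits 1-9 (digits are recycled after closing).  A '='
    precedes double bonds, including both occurrences of a ring digit.
    """
    if spec is None:
        spec = SpellingSpec(root=0)
    spec.validate_for(g)
    adj = g.adjacency()
    order_of = {(min(i, j), max(i, j)): o for i, j, o in g.bonds}

    # Pass 1: DFS in spec order classifying edges into tree children and
    # ring-closure back edges; record preorder emission positions.
    visited = [False] * g.n_atoms
    tree_children: Dict[int, List[int]] = {i: [] for i in range(g.n_atoms)}
    back_edges: List[Tuple[int, int]] = []  # (later atom, earlier atom)
    processed = set()
    emit_pos: Dict[int, int] = {}

    frames: List[Tuple[int, List[int], int]] = []
    visited[spec.root] = True
    emit_pos[spec.root] = 0
    frames.append(
        (spec.root, spec.order_for(spec.root, [j for j, _ in adj[spec.root]]), 0)
    )
    while frames:
        atom, ordered, idx = frames.pop()
        descended = False
        while idx < len(ordered):
            nb = ordered[idx]
            idx += 1
            ekey = (min(atom, nb), max(atom, nb))
            if ekey in processed:
                continue
            processed.add(ekey)
            if visited[nb]:
                back_edges.append((atom, nb))
            else:
                visited[nb] = True
                emit_pos[nb] = len(emit_pos)
                tree_children[atom].append(nb)
                frames.append((atom, ordered, idx))
                frames.append((nb, spec.order_for(nb, [j for j, _ in adj[nb]]), 0))
                descended = True
                break
        if descended:
            continue

    # Pass 2: plan ring digits.  Each back edge opens at the earlier-emitted
    # atom and closes at the later one; openings are sorted by (open, close)
    # position so digit assignment follows string order.
    opens_at: Dict[int, List[int]] = {i: [] for i in range(g.n_atoms)}
    closes_at: Dict[int, List[int]] = {i: [] for i in range(g.n_atoms)}
    events = []
    for a, b in back_edges:
        opener, closer = (a, b) if emit_pos[a] < emit_pos[b] else (b, a)
        events.append((emit_pos[opener], emit_pos[closer], opener, closer))
    for _, _, opener, closer in sorted(events):
        opens_at[opener].append(closer)
        closes_at[closer].append(opener)

    digit_free = list(range(1, 10))
    digit_for: Dict[Tuple[int, int], int] = {}
    out: List[str] = []

    def emit_atom(atom: int) -> None:
        out.append(g.atoms[atom])
        for partner in opens_at[atom]:
            if not digit_free:
                raise SmilesError(">9 simultaneously open ring closures")
            d = digit_free.pop(0)
            ekey = (min(atom, partner), max(atom, partner))
            digit_for[ekey] = d
            if order_of[ekey] == 2:
                out.append("=")
            out.append(str(d))
        for partner in closes_at[atom]:
            ekey = (min(atom, partner), max(atom, partner))
            d = digit_for.pop(ekey)
            if order_of[ekey] == 2:
                out.append("=")
            out.append(str(d))
            digit_free.append(d)
            digit_free.sort()

    # Pass 3: emit, iteratively to keep spelling independent of recursion
    # limits.  Work items are atoms to write or literal punctuation.
    work: List[Tuple[str, int, int]] = [("atom", spec.root, -1)]
    while work:
        kind, payload, parent = work.pop()
        if kind == "lit":
            out.append("()"[payload])
            continue
        atom = payload
        if parent >= 0 and order_of[(min(atom, parent), max(atom, parent))] == 2:
            out.append("=")
        emit_atom(atom)
        children = tree_children[atom]
        items: List[Tuple[str, int, int]] = []
        for k, child in enumerate(children):
            if k < len(children) - 1:
                items.append(("lit", 0, -1))
                items.append(("atom", child, atom))
                items.append(("lit", 1, -1))
            else:
                items.append(("atom", child, atom))
        work.extend(reversed(items))
    return "".join(out)


_ATOM_RE = re.compile(r"Cl|Br|[CNOSF]")


def parse_smiles(s: str) -> MolGraph:
    """Parse the supported SMILES subset into a :class:`MolGraph`.

    Supported: element symbols C N O S F Cl Br, '=', branches '()', ring
    closure digits 1-9.  Errors name the offending position.
    """
    if not s:
        raise SmilesError("empty SMILES")
    atoms: List[str] = []
    bonds: List[Tuple[int, int, int]] = []
    stack: List[int] = []
    prev = -1
    pending_order = 1
    pending_explicit = False
    ring_open: Dict[str, Tuple[int, int]] = {}  # digit -> (atom, order)
    i = 0
    n = len(s)
    while i < n:
        ch = s[i]
        m = _ATOM_RE.match(s, i)
        if m:
            sym = m.group(0)
            idx = len(atoms)
            atoms.append(sym)
            if prev >= 0:
                bonds.append((min(prev, idx), max(prev, idx), pending_order))
            prev = idx
            pending_order = 1
            pending_explicit = False
            i = m.end()
            continue
        if ch == "=":
            if pending_explicit:
                raise SmilesError("consecutive bond symbols", i)
            pending_order = 2
            pending_explicit = True
            i += 1
            continue
        if ch == "(":
            if prev < 0:
                raise SmilesError("branch before any atom", i)
            stack.append(prev)
            i += 1
            continue
        if ch == ")":
            if not stack:
                raise SmilesError("unbalanced ')'", i)
            prev = stack.pop()
            i += 1
            continue
        if ch.isdigit():
            if ch == "0":
                raise SmilesError("ring digit 0 unsupported", i)
            if prev < 0:
                raise SmilesError("ring digit before any atom", i)
            if ch in ring_open:
                partner, oorder = ring_open.pop(ch)
                order = pending_order
                if pending_explicit and oorder == 2 and order != 2:
                    raise SmilesError("inconsistent ring bond order", i)
                order = max(order, oorder)
                if partner == prev:
                    raise SmilesError("ring closure to same atom", i)
                key = (min(partner, prev), max(partner, prev))
                if any((b[0], b[1]) == key for b in bonds):
                    raise SmilesError("duplicate ring bond", i)
                bonds.append((key[0], key[1], order))
            else:
                ring_open[ch] = (prev, pending_order)
            pending_order = 1
            pending_explicit = False
            i += 1
            continue
        raise SmilesError(f"unknown symbol {ch!r}", i)
    if stack:
        raise SmilesError("unbalanced '('", n - 1)
    if ring_open:
        digit = sorted(ring_open)[0]
        raise SmilesError(f"unpaired ring digit {digit}", n - 1)
    if pending_explicit:
        raise SmilesError("dangling bond symbol", n - 1)
    try:
        return MolGraph(tuple(atoms), tuple(sorted(bonds)))
    except ValueError as exc:
        raise SmilesError(str(exc)) from exc


def _wl_ranks(g: MolGraph) -> List[int]:
    """Isomorphism-invariant atom ranks via iterative neighborhood refinement.

    Initial color = (element, degree, total bond order); each round appends
    the sorted multiset of (bond order, neighbor color).  Atoms left in the
    same class after stabilization are treated as interchangeable
    (automorphic in practice for the supported molecule sizes).
    """
    adj = g.adjacency()
    used = g.valence_used()
    colors: List = [
        (g.atoms[i], len(adj[i]), used[i]) for i in range(g.n_atoms)
    ]
    for _ in range(g.n_atoms):
        palette = sorted(set(colors))
        rank = {c: k for k, c in enumerate(palette)}
        new_colors = [
            (rank[colors[i]], tuple(sorted((o, rank[colors[j]]) for j, o in adj[i])))
            for i in range(g.n_atoms)
        ]
        if len(set(new_colors)) == len(set(colors)):
            colors = new_colors
            break
        colors = new_colors
    palette = sorted(set(colors))
    rank = {c: k for k, c in enumerate(palette)}
    return [rank[c] for c in colors]


def canonical_spec(g: MolGraph) -> SpellingSpec:
    """Deterministic, isomorphism-invariant spelling spec.

    Root = atom of minimal (refined rank, degree, element); neighbors
    visited in ascending (refined rank, degree, element) order.  Remaining
    ties are broken by atom index, which only matters between atoms the
    refinement could not distinguish.
    """
    ranks = _wl_ranks(g)
    adj = g.adjacency()

    def key(i: int):
        return (ranks[i], len(adj[i]), g.atoms[i], i)

    root = min(range(g.n_atoms), key=key)
    neighbor_order = {
        i: sorted((j for j, _ in adj[i]), key=key) for i in range(g.n_atoms)
    }
    return SpellingSpec(root=root, neighbor_order=neighbor_order)


def canonical_smiles(g_or_s: "MolGraph | str") -> str:
    """Canonical spelling of a graph (or of a SMILES string's molecule)."""
    g = parse_smiles(g_or_s) if isinstance(g_or_s, str) else g_or_s
    return write_smiles(g, canonical_spec(g))


def random_spec(g: MolGraph, rng: np.random.Generator) -> SpellingSpec:
    """Uniformly random root and per-atom neighbor permutations."""
    adj = g.adjacency()
    root = int(rng.integers(g.n_atoms))
    neighbor_order = {}
    for i in range(g.n_atoms):
        neigh = [j for j, _ in adj[i]]
        perm = list(rng.permutation(len(neigh)))
        neighbor_order[i] = [neigh[k] for k in perm]
    return SpellingSpec(root=root, neighbor_order=neighbor_order)


def enumerate_smiles(s: str, rng_seed=0) -> str:
    """A random alternative spelling of the molecule ``s`` denotes.

    Draws a uniformly random traversal root and neighbor orders; the result
    always parses back to the same molecule.  Single-spelling molecules
    (e.g. ``C``... strictly, any molecule whose every spelling coincides)
    return the input spelling.
    """
    rng = _as_rng(rng_seed)
    g = parse_smiles(s)
    return write_smiles(g, random_spec(g, rng))


_LABEL_TASKS = ("contains_double_bond", "ring_count", "oxygen_count")


def synthetic_labels(g: MolGraph, task: str) -> int:
    """Structure-determined labels for fine-tuning experiments.

    contains_double_bond: 1 iff any bond has order 2.
    ring_count: cyclomatic number, bonds - atoms + 1.
    oxygen_count: number of O atoms.
    """
    if task == "contains_double_bond":
        return int(any(o == 2 for _, _, o in g.bonds))
    if task == "ring_count":
        return len(g.bonds) - g.n_atoms + 1
    if task == "oxygen_count":
        return sum(1 for a in g.atoms if a == "O")
    raise ValueError(f"unknown task {task!r}; expected one of {_LABEL_TASKS}")


def six_membered_ring_count(g: MolGraph) -> int:
    """Number of simple 6-cycles, a benzene-ring proxy on this subset."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in g.bonds)
    return sum(1 for cyc in nx.simple_cycles(G, length_bound=6) if len(cyc) == 6)


def generate_corpus(
    n_molecules: int,
    min_atoms: int = 4,
    max_atoms: int = 25,
    ring_prob: float = 0.3,
    rng_seed=0,
) -> List[str]:
    """Canonical SMILES for ``n_molecules`` distinct random molecules."""
    rng = _as_rng(rng_seed)
    seen = set()
    out: List[str] = []
    attempts = 0
    while len(out) < n_molecules:
        attempts += 1
        if attempts > 50 * n_molecules:
            raise RuntimeError("could not generate enough distinct molecules")
        n_atoms = int(rng.integers(min_atoms, max_atoms + 1))
        g = random_molecule(n_atoms, ring_prob, rng)
        s = canonical_smiles(g)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def write_corpus(path, smiles: Iterable[str]) -> None:
    """One SMILES per line — the pretraining corpus format."""
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


def read_corpus(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
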