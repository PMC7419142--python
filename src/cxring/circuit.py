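"""Construction of the heading-circuit connectivity matrices.

The protocerebral bridge (PB) of each hemisphere holds ``n_glom``
glomeruli, numbered 1..n left-to-right in *both* hemispheres; the
ellipsoid body (EB) holds eight tiles.  The fruit fly has nine glomeruli
per hemisphere, the locust eight.  Each glomerulus is served by one
neuron per columnar class (E-PG, P-EN, P-EG), and eight Delta7 identities
span the PB.  Functionally the circuit folds onto eight "octants" (45°
sectors); glomerulus g maps to octant (g-1) mod 8, so the fly's ninth
glomerulus shares octant 0 with the first (tile T1 is innervated by both
E-PG_1 and E-PG_9).

Projection rules realised here:

* E-PG -> P-EN and P-EG within the same glomerulus (and, in the locust,
  the medial E-PGs cross-innervate both medial glomeruli, closing the
  ring at the open end of the crescent-shaped EB).
* P-EN -> E-PG shifted one whole tile (fly) or one half tile (locust);
  the half-tile shift additionally yields a reciprocal same-octant
  connection.
* P-EG -> E-PG reciprocally through the same tile.
* E-PG -> Delta7: uniform across glomeruli (fly) or weighted by the
  Delta7 dendritic Gaussian profile (locust).
* Delta7 -> P-EN/P-EG at the Delta7's output glomeruli; Delta7 -> Delta7
  all-to-all (fly) or Gaussian-profile weighted (locust).

The hybrid model is the fly circuit with the two Delta7-related rules
replaced by locust-style Gaussian profiles over nine glomeruli.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CLASSES = ("E-PG", "P-EN", "P-EG", "Delta7")
SPECIES = ("fly", "locust", "hybrid")

#: Gaussian width of the locust Delta7 dendritic profile (glomerulus
#: coordinate units); estimated from dendritic density in dye fills.
DEFAULT_SIGMA = 0.8


class CircuitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weight vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    """The five free synaptic-class strengths (PSC equivalents per AP).

    w1: E-PG -> {P-EN, P-EG, Delta7}   (excitatory, 0..100)
    w2: P-EN -> E-PG                   (excitatory, 0..100)
    w3: P-EG -> E-PG                   (excitatory, 0..100)
    w4: Delta7 -> {P-EN, P-EG}         (inhibitory, -100..0)
    w5: Delta7 -> Delta7               (inhibitory, -100..0)
    """

    w1: float
    w2: float
    w3: float
    w4: float
    w5: float

    BOUNDS = ((0.0, 100.0), (0.0, 100.0), (0.0, 100.0), (-100.0, 0.0), (-100.0, 0.0))

    def __post_init__(self):
        arr = self.as_array()
        for v, (lo, hi) in zip(arr, self.BOUNDS):
            if not (lo <= v <= hi):
                raise CircuitError(f"weight {v} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5])

    @classmethod
    def from_array(cls, arr) -> "WeightVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise CircuitError("weight vector must have 5 entries")
        return cls(*arr.tolist())

    @classmethod
    def initial(cls) -> "WeightVector":
        """Optimiser initialisation: +-0.01 matching each bound's sign."""
        return cls(0.01, 0.01, 0.01, -0.01, -0.01)

    @classmethod
    def zeros(cls) -> "WeightVector":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WeightVector":
        return cls(**{k: d[k] for k in ("w1", "w2", "w3", "w4", "w5")})


# ---------------------------------------------------------------------------
# Delta7 dendritic profile
# ---------------------------------------------------------------------------

def delta7_inhibition_profile(i: int, n: int, sigma: float, W: float) -> float:
    """Gaussian synaptic-density profile across the PB glomeruli.

    ``w(i) = W / (sigma sqrt(2 pi)) * exp(-((i-1) 2 pi / n - pi)^2 / (2 sigma^2))``

    for glomerulus ``i`` in 1..n of one hemisphere.  The profile peaks at
    the glomerulus diametrically opposite the Delta7's output branches
    and is minimal at the output glomerulus itself (dendrites avoid the
    regions around the output branches).
    """
    if not 1 <= i <= n:
        raise CircuitError(f"glomerulus index {i} out of range 1..{n}")
    if sigma <= 0:
        raise CircuitError("sigma must be positive")
    mu = np.pi
    z = ((i - 1) / n * 2.0 * np.pi - mu) / sigma
    return W / (sigma * np.sqrt(2.0 * np.pi)) * float(np.exp(-0.5 * z * z))


def _profile_at(glom: int, centre: int, n: int, sigma: float, W: float) -> float:
    """Profile value at ``glom`` for a Delta7 whose output branch sits at
    ``centre`` (both 1-based, same hemisphere): the canonical profile is
    rotated circularly so its minimum falls on the output glomerulus."""
    shifted = ((glom - centre) % n) + 1
    return delta7_inhibition_profile(shifted, n, sigma, W)


# ---------------------------------------------------------------------------
# Circuit container
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Signed, weighted adjacency of a species circuit.

    ``M[j, i]`` is the weight from presynaptic neuron j onto postsynaptic
    neuron i, in PSC-template equivalents per action potential.
    """

    M: np.ndarray
    neurons: pd.DataFrame      # columns: label, cls, hemi, glom, octant
    species: str
    sigma: Optional[float]
    weights: WeightVector
    n_octants: int = 8
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return self.neurons["label"].tolist()

    @property
    def n_neurons(self) -> int:
        return self.M.shape[0]

    def class_indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero((self.neurons["cls"] == cls).to_numpy())

    def octants(self, cls: str) -> np.ndarray:
        """Octant index of each neuron of ``cls`` (order as in the matrix)."""
        sel = self.neurons["cls"] == cls
        return self.neurons.loc[sel, "octant"].to_numpy()

    def azimuths(self, cls: str) -> np.ndarray:
        """EB-domain azimuth (deg) of each neuron of ``cls``."""
        sel = self.neurons["cls"] == cls
        return self.neurons.loc[sel, "azimuth"].to_numpy()

    def index(self, cls: str, hemi: str = "", glom: int = -1) -> int:
        sel = self.neurons[
            (self.neurons["cls"] == cls)
            & (self.neurons["hemi"] == hemi)
            & (self.neurons["glom"] == glom)
        ]
        if len(sel) != 1:
            raise CircuitError(f"no unique neuron ({cls}, {hemi}, {glom})")
        return int(sel.index[0])

    # ---- serialisation -------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Labelled square CSV, row = presynaptic neuron."""
        df = pd.DataFrame(self.M, index=self.labels, columns=self.labels)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, species: str = "unknown",
                 weights: Optional[WeightVector] = None) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = list(df.index)
        neurons = _table_from_labels(labels)
        return cls(M=df.to_numpy(float), neurons=neurons, species=species,
                   sigma=None, weights=weights or WeightVector.zeros())

    def to_adjacency_json(self, path: str | Path) -> None:
        adj = {
            "species": self.species,
            "labels": self.labels,
            "edges": [
                {"pre": self.labels[j], "post": self.labels[i], "w": float(self.M[j, i])}
                for j, i in zip(*np.nonzero(self.M))
            ],
        }
        with open(path, "w") as fh:
            json.dump(adj, fh, indent=1)

    def to_dot(self, path: str | Path) -> None:
        lines = ["digraph circuit {"]
        for j, i in zip(*np.nonzero(self.M)):
            colour = "red" if self.M[j, i] < 0 else "black"
            lines.append(
                f'  "{self.labels[j]}" -> "{self.labels[i]}" '
                f'[color={colour}, weight={abs(self.M[j, i]):.3f}];'
            )
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def _table_from_labels(labels: list[str]) -> pd.DataFrame:
    # azimuths fall back to octant centres when species context is absent
    rows = []
    for lab in labels:
        cls, rest = lab.split("_", 1)
        if cls == "Delta7":
            d = int(rest)
            rows.append({"label": lab, "cls": cls, "hemi": "", "glom": -1,
                         "octant": d, "azimuth": d * 45.0})
        else:
            hemi, g = rest[0], int(rest[1:])
            o = (g - 1) % 8
            rows.append({"label": lab, "cls": cls, "hemi": hemi, "glom": g,
                         "octant": o, "azimuth": o * 45.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inventory
# ---------------------------------------------------------------------------

def _azimuth(cls: str, hemi: str, octant: int, species: str, n_oct: int) -> float:
    """EB azimuth (degrees) of a neuron's synaptic domain centre.

    Tiles are 360/n_oct wide, tile x centred at (x-1)*span; wedges are
    half tiles.  Fly E-PG neurons occupy single wedges (the two
    hemisphere members of a unit flank their tile centre), locust E-PG
    units span the boundary of two neighbouring tiles (half-tile offset
    toward increasing azimuth).  P-EN domains are whole tiles shifted by
    one tile (fly) or half a tile (locust); fly P-EG domains are whole
    tiles, locust P-EG domains mirror the E-PG wedges.  Delta7 azimuths
    are their output octant centres.
    """
    span = 360.0 / n_oct
    quarter = span / 4.0
    fly_like = species in ("fly", "hybrid")
    if cls == "Delta7":
        return (octant * span) % 360.0
    if cls == "E-PG" or (cls == "P-EG" and not fly_like):
        if fly_like:
            return (octant * span + (-quarter if hemi == "L" else quarter)) % 360.0
        return (octant * span + (quarter if hemi == "L" else 3 * quarter)) % 360.0
    if cls == "P-EG":
        return (octant * span) % 360.0
    # P-EN: fly domains sit one whole tile to the side; locust domains
    # cover the next tile (left) or the home tile (right), one wedge
    # shifted relative to the same-numbered E-PG unit
    if fly_like:
        shift = span if hemi == "L" else -span
    else:
        shift = span if hemi == "L" else 0.0
    return (octant * span + shift) % 360.0


def _inventory(species: str, n_oct: int) -> pd.DataFrame:
    if species not in SPECIES:
        raise CircuitError(f"unknown species: {species!r}")
    fly_like = species in ("fly", "hybrid")
    n_glom = n_oct + 1 if fly_like else n_oct
    rows = []

    def octant(g):
        return (g - 1) % n_oct

    def add(cls, hemi, g, oct_):
        rows.append({
            "label": f"{cls}_{hemi}{g}" if cls != "Delta7" else f"Delta7_{oct_}",
            "cls": cls, "hemi": hemi, "glom": g, "octant": oct_,
            "azimuth": _azimuth(cls, hemi, oct_, species, n_oct),
        })

    for hemi in "LR":
        for g in range(1, n_glom + 1):
            add("E-PG", hemi, g, octant(g))
    for hemi in "LR":
        for g in range(1, n_glom + 1):
            if fly_like:
                # no P-EN in the innermost glomeruli (left G9, right G1)
                if (hemi == "L" and g == n_glom) or (hemi == "R" and g == 1):
                    continue
            add("P-EN", hemi, g, octant(g))
    for hemi in "LR":
        for g in range(1, n_glom + 1):
            add("P-EG", hemi, g, octant(g))
    for d in range(n_oct):
        add("Delta7", "", -1, d)
    return pd.DataFrame(rows)


def _delta7_output_gloms(d: int, n_glom: int, n_oct: int) -> list[int]:
    """Per-hemisphere output glomeruli of Delta7 identity ``d``: every
    glomerulus whose octant is d (the identity at the seam also claims the
    wrap glomerulus in the fly's nine-glomerulus bridge)."""
    return [g for g in range(1, n_glom + 1) if (g - 1) % n_oct == d]


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def build_species_circuit(
    species: str,
    weights: WeightVector,
    sigma: float = DEFAULT_SIGMA,
    n_octants: int = 8,
) -> ConnectivityMatrix:
    """Build the signed connectivity matrix for one species.

    ``n_octants`` scales the whole construction down for fast tests (the
    default 8 is the anatomical circuit).
    """
    if species not in SPECIES:
        raise CircuitError(f"unknown species: {species!r}")
    if sigma <= 0:
        raise CircuitError("sigma must be positive")
    n_oct = n_octants
    neurons = _inventory(species, n_oct)
    n = len(neurons)
    M = np.zeros((n, n))
    fly_like = species in ("fly", "hybrid")
    n_glom = n_oct + 1 if fly_like else n_oct
    local_inhibition = species in ("locust", "hybrid")

    idx = {(r.cls, r.hemi, r.glom): i for i, r in neurons.iterrows()}
    d7_idx = {r.octant: i for i, r in neurons.iterrows() if r.cls == "Delta7"}

    def epg_of_octant(o):
        return [i for i, r in neurons.iterrows()
                if r.cls == "E-PG" and r.octant == o]

    def octant(g):
        return (g - 1) % n_oct

    w = weights

    # (a) E-PG -> P-EN, P-EG within the same glomerulus
    for hemi in "LR":
        for g in range(1, n_glom + 1):
            src = idx[("E-PG", hemi, g)]
            for cls in ("P-EN", "P-EG"):
                tgt = idx.get((cls, hemi, g))
                if tgt is not None:
                    M[src, tgt] = w.w1
    if species == "locust":
        # medial E-PGs cross-innervate both medial glomeruli (ring closure)
        for (h_src, g_src), (h_tgt, g_tgt) in (
            (("L", n_glom), ("R", 1)),
            (("R", 1), ("L", n_glom)),
        ):
            src = idx[("E-PG", h_src, g_src)]
            for cls in ("P-EN", "P-EG"):
                M[src, idx[(cls, h_tgt, g_tgt)]] = w.w1

    # (e) E-PG -> Delta7
    for i, r in neurons[neurons["cls"] == "E-PG"].iterrows():
        for d in range(n_oct):
            tgt = d7_idx[d]
            if local_inhibition:
                centres = _delta7_output_gloms(d, n_glom, n_oct)
                val = np.mean([
                    _profile_at(r.glom, c, n_glom, sigma, w.w1) for c in centres
                ])
                M[i, tgt] = val
            else:
                M[i, tgt] = w.w1

    # (b, c) P-EN -> E-PG
    for i, r in neurons[neurons["cls"] == "P-EN"].iterrows():
        o = r.octant
        if species in ("fly", "hybrid"):
            # whole-tile shift: every E-PG wedge of the neighbouring tile
            shift = 1 if r.hemi == "L" else -1
            for tgt in epg_of_octant((o + shift) % n_oct):
                M[i, tgt] = w.w2
        else:
            # half-tile shift: the tile-wide P-EN domain overlaps one
            # wedge of the same-octant E-PG unit (reciprocal) and one
            # wedge of the neighbouring unit; no wrap across the open
            # end of the EB (ring closure comes from the PB medial
            # cross-innervation)
            if r.hemi == "L":
                wedge_targets = [("R", o), ("L", o + 1)]
            else:
                wedge_targets = [("R", o - 1), ("L", o)]
            for hemi_t, o_t in wedge_targets:
                if not 0 <= o_t < n_oct:
                    continue
                tgt = idx.get(("E-PG", hemi_t, o_t + 1))
                if tgt is not None:
                    M[i, tgt] = w.w2

    # (d) P-EG -> E-PG through the same tile (fly) / same wedge (locust)
    for i, r in neurons[neurons["cls"] == "P-EG"].iterrows():
        if species in ("fly", "hybrid"):
            for tgt in epg_of_octant(r.octant):
                M[i, tgt] = w.w3
        else:
            tgt = idx.get(("E-PG", r.hemi, r.glom))
            if tgt is not None:
                M[i, tgt] = w.w3

    # (f) Delta7 -> P-EN, P-EG at its output glomeruli
    for d in range(n_oct):
        src = d7_idx[d]
        for i, r in neurons.iterrows():
            if r.cls in ("P-EN", "P-EG") and r.octant == d:
                M[src, i] = w.w4

    # (g) Delta7 -> Delta7
    for d_pre in range(n_oct):
        src = d7_idx[d_pre]
        for d_post in range(n_oct):
            if d_post == d_pre:
                continue
            tgt = d7_idx[d_post]
            if local_inhibition:
                pre_out = _delta7_output_gloms(d_pre, n_glom, n_oct)
                post_centres = _delta7_output_gloms(d_post, n_glom, n_oct)
                vals = [
                    _profile_at(g, c, n_glom, sigma, w.w5)
                    for g in pre_out for c in post_centres
                ]
                M[src, tgt] = float(np.mean(vals))
            else:
                M[src, tgt] = w.w5

    return ConnectivityMatrix(
        M=M, neurons=neurons, species=species,
        sigma=sigma if local_inhibition else None,
        weights=weights, n_octants=n_oct,
        meta={"n_glomeruli_per_hemisphere": n_glom},
    )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def remove_peg(circuit: ConnectivityMatrix) -> ConnectivityMatrix:
    """Delete all P-EG neurons (rows and columns)."""
    keep = np.flatnonzero((circuit.neurons["cls"] != "P-EG").to_numpy())
    neurons = circuit.neurons.iloc[keep].reset_index(drop=True)
    M = circuit.M[np.ix_(keep, keep)]
    return ConnectivityMatrix(
        M=M, neurons=neurons, species=circuit.species, sigma=circuit.sigma,
        weights=circuit.weights, n_octants=circuit.n_octants,
        meta={**circuit.meta, "variant": "remove_PEG"},
    )


def hemisphere_asymmetry(
    circuit: ConnectivityMatrix, factor: float, hemisphere: str = "R"
) -> ConnectivityMatrix:
    """Scale all P-EN -> E-PG weights of one hemisphere by (1 + factor)."""
    if not -1.0 <= factor <= 1.0:
        raise CircuitError("asymmetry factor must be within [-1, 1]")
    if hemisphere not in ("L", "R"):
        raise CircuitError("hemisphere must be 'L' or 'R'")
    M = circuit.M.copy()
    pre = ((circuit.neurons["cls"] == "P-EN")
           & (circuit.neurons["hemi"] == hemisphere)).to_numpy()
    post = (circuit.neurons["cls"] == "E-PG").to_numpy()
    M[np.ix_(pre, post)] *= (1.0 + factor)
    return ConnectivityMatrix(
        M=M, neurons=circuit.neurons, species=circuit.species,
        sigma=circuit.sigma, weights=circuit.weights,
        n_octants=circuit.n_octants,
        meta={**circuit.meta, "variant": f"asymmetry({factor:+.2f}, {hemisphere})"},
    )


def synaptic_noise(
    circuit: ConnectivityMatrix, x: float, rng: np.random.Generator
) -> ConnectivityMatrix:
    """Additive white Gaussian noise on every nonzero synaptic weight:
    ``v = v_nominal (1 + (x/100) eps)`` with eps ~ N(0, 1)."""
    if not 0 <= x <= 100:
        raise CircuitError("noise level x must be within [0, 100]")
    M = circuit.M.copy()
    jj, ii = np.nonzero(M)
    eps = rng.standard_normal(jj.size)
    M[jj, ii] = M[jj, ii] * (1.0 + x / 100.0 * eps)
    return ConnectivityMatrix(
        M=M, neurons=circuit.neurons, species=circuit.species,
        sigma=circuit.sigma, weights=circuit.weights,
        n_octants=circuit.n_octants,
        meta={**circuit.meta, "variant": f"synaptic_noise({x}%)"},
    )


def apply_variant(circuit: ConnectivityMatrix, variant: str, **kw) -> ConnectivityMatrix:
    """Dispatch by variant name: remove_PEG | hemisphere_asymmetry | synaptic_noise."""
    if variant == "remove_PEG":
        return remove_peg(circuit)
    if variant == "hemisphere_asymmetry":
        return hemisphere_asymmetry(circuit, **kw)
    if variant == "synaptic_noise":
        return synaptic_noise(circuit, **kw)
    raise CircuitError(f"unknown variant: {variant!r}")


# ---------------------------------------------------------------------------
# Structure checks (used by tests and the fixture generator)
# ---------------------------------------------------------------------------

def unit_graph(circuit: ConnectivityMatrix):
    """Collapse hemisphere pairs (and the fly G1/G9 merge) into one unit
    per (class, octant) and return the unit-level digraph."""
    import networkx as nx

    g = nx.DiGraph()
    units = {}
    for i, r in circuit.neurons.iterrows():
        u = (r.cls, int(r.octant))
        units[i] = u
        g.add_node(u)
    jj, ii = np.nonzero(circuit.M)
    for j, i in zip(jj, ii):
        g.add_edge(units[j], units[i])
    return g


def epg_transition_octants(circuit: ConnectivityMatrix) -> set[tuple[int, int]]:
    """Octant-level E-PG -> E-PG transitions through P-EN edges (two-step
    reachability E-PG -> P-EN -> E-PG), excluding self transitions."""
    out = set()
    epg = circuit.class_indices("E-PG")
    pen = circuit.class_indices("P-EN")
    octs = circuit.neurons["octant"].to_numpy()
    for a in epg:
        for p in pen:
            if circuit.M[a, p] == 0:
                continue
            for b in epg:
                if circuit.M[p, b] != 0 and octs[a] != octs[b]:
                    out.add((int(octs[a]), int(octs[b])))
    return out
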