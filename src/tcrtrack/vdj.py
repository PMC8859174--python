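"""Simplified V(D)J recombination model for TCR-beta junctions.

The generative process mirrors the standard recombination statistics used by
repertoire-modelling tools (IGoR/OLGA-style), reduced to a desk-scale
parameterization:

1. choose a V segment (its 3' flank starts at the conserved cysteine codon),
   delete ``delV`` bases from its 3' end;
2. insert ``nVD`` random bases (i.i.d. nucleotide distribution);
3. choose a D segment, delete ``del5``/``del3`` bases from its ends;
4. insert ``nDJ`` random bases;
5. choose a J segment (its 5' flank ends at the conserved phenylalanine
   codon), delete ``delJ`` bases from its 5' end.

The junction (CDR3) nucleotide string is the concatenation of the surviving
pieces.  ``pgen_nt`` marginalizes the recombination scenario by a forward
dynamic program over an automaton whose states encode (V-prefix position) x
(insertion progress) x (D placement) x (J-suffix position); ``pgen_aa``
additionally marginalizes synonymous codon choices by branching the same
forward pass over the codons of each amino acid.  ``enumerate_scenarios`` is
an independent exhaustive oracle for small models.

Deviations from the published TCR-beta models, chosen to keep the scenario
space exactly enumerable: D usage is independent of J, there are no
palindromic (negative) deletions, and insertion nucleotides are i.i.d.
rather than Markov.  Deletion distributions have bounded support such that
``max(del5) + max(del3) <= len(D)`` (and likewise for V/J), so independent
deletion draws always realize a valid scenario and total probability mass
over sequences is exactly 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio.Seq import Seq

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}

# amino acid -> codons (standard genetic code, stops excluded)
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon in ("".join(t) for t in itertools.product(NT, repeat=3)):
    _aa = str(Seq(_codon).translate())
    if _aa != "*":
        CODONS_FOR_AA.setdefault(_aa, ())
        CODONS_FOR_AA[_aa] += (_codon,)


class ModelError(ValueError):
    """Raised when a generative model violates its invariants."""


def _check_dist(p: np.ndarray, name: str) -> None:
    if np.any(p < 0):
        raise ModelError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ModelError(f"{name} does not sum to 1 (sum={p.sum()!r})")


def _support_max(p: np.ndarray) -> int:
    nz = np.nonzero(p)[0]
    return int(nz[-1]) if len(nz) else 0


@dataclass
class GenerativeModel:
    """Segment sequences and probability distributions of the V(D)J process."""

    v_names: list[str]
    v_seqs: list[str]
    p_v: np.ndarray
    d_names: list[str]
    d_seqs: list[str]
    p_d: np.ndarray
    j_names: list[str]
    j_seqs: list[str]
    p_j: np.ndarray
    p_del_v: np.ndarray  # (nV, max_del_v + 1)
    p_del_j: np.ndarray  # (nJ, max_del_j + 1)
    p_del5: np.ndarray  # (nD, max_del5 + 1)
    p_del3: np.ndarray  # (nD, max_del3 + 1)
    p_ins_vd: np.ndarray
    p_ins_dj: np.ndarray
    p_nt: np.ndarray  # over ACGT
    _automata: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for attr in ("p_v", "p_d", "p_j", "p_del_v", "p_del_j", "p_del5",
                     "p_del3", "p_ins_vd", "p_ins_dj", "p_nt"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        self.validate()

    def validate(self) -> None:
        for seqs, name in ((self.v_seqs, "V"), (self.d_seqs, "D"), (self.j_seqs, "J")):
            if not seqs or any(not s for s in seqs):
                raise ModelError(f"{name} segment sequences must be non-empty")
            for s in seqs:
                if set(s) - set(NT):
                    raise ModelError(f"{name} segment {s!r} has non-ACGT letters")
        _check_dist(self.p_v, "P(V)")
        _check_dist(self.p_d, "P(D)")
        _check_dist(self.p_j, "P(J)")
        _check_dist(self.p_ins_vd, "P(nVD)")
        _check_dist(self.p_ins_dj, "P(nDJ)")
        _check_dist(self.p_nt, "p(nt)")
        for i, seq in enumerate(self.v_seqs):
            _check_dist(self.p_del_v[i], f"P(delV|{self.v_names[i]})")
            if _support_max(self.p_del_v[i]) > len(seq):
                raise ModelError(f"delV support exceeds V flank length for {self.v_names[i]}")
        for i, seq in enumerate(self.j_seqs):
            _check_dist(self.p_del_j[i], f"P(delJ|{self.j_names[i]})")
            if _support_max(self.p_del_j[i]) > len(seq):
                raise ModelError(f"delJ support exceeds J flank length for {self.j_names[i]}")
        for i, seq in enumerate(self.d_seqs):
            _check_dist(self.p_del5[i], f"P(del5|{self.d_names[i]})")
            _check_dist(self.p_del3[i], f"P(del3|{self.d_names[i]})")
            if _support_max(self.p_del5[i]) + _support_max(self.p_del3[i]) > len(seq):
                raise ModelError(
                    f"del5+del3 support exceeds D length for {self.d_names[i]}"
                )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "v_segments": [
                {"name": n, "seq": s, "p": float(p), "p_del": self.p_del_v[i].tolist()}
                for i, (n, s, p) in enumerate(zip(self.v_names, self.v_seqs, self.p_v))
            ],
            "d_segments": [
                {
                    "name": n,
                    "seq": s,
                    "p": float(p),
                    "p_del5": self.p_del5[i].tolist(),
                    "p_del3": self.p_del3[i].tolist(),
                }
                for i, (n, s, p) in enumerate(zip(self.d_names, self.d_seqs, self.p_d))
            ],
            "j_segments": [
                {"name": n, "seq": s, "p": float(p), "p_del": self.p_del_j[i].tolist()}
                for i, (n, s, p) in enumerate(zip(self.j_names, self.j_seqs, self.p_j))
            ],
            "p_ins_vd": self.p_ins_vd.tolist(),
            "p_ins_dj": self.p_ins_dj.tolist(),
            "p_nt": {c: float(self.p_nt[i]) for i, c in enumerate(NT)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        vs, ds, js = d["v_segments"], d["d_segments"], d["j_segments"]

        def pad(rows):
            width = max(len(r) for r in rows)
            return np.array([list(r) + [0.0] * (width - len(r)) for r in rows])

        return cls(
            v_names=[x["name"] for x in vs],
            v_seqs=[x["seq"] for x in vs],
            p_v=np.array([x["p"] for x in vs]),
            d_names=[x["name"] for x in ds],
            d_seqs=[x["seq"] for x in ds],
            p_d=np.array([x["p"] for x in ds]),
            j_names=[x["name"] for x in js],
            j_seqs=[x["seq"] for x in js],
            p_j=np.array([x["p"] for x in js]),
            p_del_v=pad([x["p_del"] for x in vs]),
            p_del_j=pad([x["p_del"] for x in js]),
            p_del5=pad([x["p_del5"] for x in ds]),
            p_del3=pad([x["p_del3"] for x in ds]),
            p_ins_vd=np.array(d["p_ins_vd"]),
            p_ins_dj=np.array(d["p_ins_dj"]),
            p_nt=np.array([d["p_nt"][c] for c in NT]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- convenience --------------------------------------------------------

    def v_index(self, name: str) -> int:
        return self.v_names.index(name)

    def j_index(self, name: str) -> int:
        return self.j_names.index(name)

    def automaton(self, v_idx: int | None = None, j_idx: int | None = None) -> "_Automaton":
        key = (v_idx, j_idx)
        if key not in self._automata:
            self._automata[key] = _Automaton(self, v_idx, j_idx)
        return self._automata[key]


@dataclass(frozen=True)
class RecombinationScenario:
    """A fully specified recombination event (the latent variable of P_GEN)."""

    v_choice: int
    d_choice: int
    j_choice: int
    del_v: int
    del5: int
    del3: int
    del_j: int
    ins_vd: str
    ins_dj: str

    def realize(self, model: GenerativeModel) -> str:
        v = model.v_seqs[self.v_choice]
        d = model.d_seqs[self.d_choice]
        j = model.j_seqs[self.j_choice]
        return (
            v[: len(v) - self.del_v]
            + self.ins_vd
            + d[self.del5 : len(d) - self.del3]
            + self.ins_dj
            + j[self.del_j :]
        )

    def probability(self, model: GenerativeModel) -> float:
        p = (
            model.p_v[self.v_choice]
            * model.p_del_v[self.v_choice][self.del_v]
            * model.p_d[self.d_choice]
            * model.p_del5[self.d_choice][self.del5]
            * model.p_del3[self.d_choice][self.del3]
            * model.p_j[self.j_choice]
            * model.p_del_j[self.j_choice][self.del_j]
            * model.p_ins_vd[len(self.ins_vd)]
            * model.p_ins_dj[len(self.ins_dj)]
        )
        for c in self.ins_vd + self.ins_dj:
            p *= model.p_nt[NT_INDEX[c]]
        return float(p)


# ---------------------------------------------------------------------------
# Forward automaton


class _Automaton:
    """Weighted automaton over recombination states, one emission per base.

    Emitting states:
      ('V', v, k)         about to emit base k of V flank v
      ('NVD', r)          r VD-insertion bases remain (emits a free base)
      ('D', d, del5, k)   about to emit base k of D segment d
      ('NDJ', r)          r DJ-insertion bases remain
      ('J', j, b, t)      about to emit base t of the length-b J suffix

    Scenario-probability factors attach to the epsilon transitions between
    regions (segment/deletion/insertion-length choices); free emissions carry
    the insertion nucleotide probability.  Each accepting path corresponds to
    exactly one recombination scenario with the path weight equal to the
    scenario probability, so a forward pass sums scenario probabilities.
    """

    def __init__(self, model: GenerativeModel, v_idx: int | None, j_idx: int | None):
        p_v = np.zeros_like(model.p_v)
        if v_idx is None:
            p_v[:] = model.p_v
        else:
            p_v[v_idx] = model.p_v[v_idx]  # joint restriction, not conditional
        p_j = np.zeros_like(model.p_j)
        if j_idx is None:
            p_j[:] = model.p_j
        else:
            p_j[j_idx] = model.p_j[j_idx]

        states: list[tuple] = []
        index: dict[tuple, int] = {}

        def sid(state: tuple) -> int:
            if state not in index:
                index[state] = len(states)
                states.append(state)
            return index[state]

        m = model
        # --- epsilon closures, built back-to-front (preJ -> preNDJ -> preD -> postV)
        ACCEPT = "accept"

        def dget(p_row, k):
            return float(p_row[k]) if 0 <= k < len(p_row) else 0.0

        pre_j: dict = {}
        accept_w = 0.0
        for j, seq in enumerate(m.j_seqs):
            if p_j[j] == 0:
                continue
            lj = len(seq)
            for b in range(0, lj + 1):
                w = p_j[j] * dget(m.p_del_j[j], lj - b)
                if w == 0:
                    continue
                if b == 0:
                    accept_w += w
                else:
                    pre_j[sid(("J", j, b, 0))] = pre_j.get(sid(("J", j, b, 0)), 0.0) + w
        pre_j[ACCEPT] = accept_w

        def combine(target: dict, closure: dict, w: float) -> None:
            if w == 0:
                return
            for s, cw in closure.items():
                target[s] = target.get(s, 0.0) + w * cw

        pre_ndj: dict = {}
        for r in range(1, len(m.p_ins_dj)):
            if m.p_ins_dj[r] > 0:
                pre_ndj[sid(("NDJ", r))] = float(m.p_ins_dj[r])
        combine(pre_ndj, pre_j, float(m.p_ins_dj[0]))

        pre_d: dict = {}
        full_del_w = 0.0
        for d, seq in enumerate(m.d_seqs):
            ld = len(seq)
            for d5 in range(0, min(ld, len(m.p_del5[d]) - 1) + 1):
                w5 = m.p_d[d] * m.p_del5[d][d5]
                if w5 == 0:
                    continue
                if d5 < ld:
                    s = sid(("D", d, d5, d5))
                    pre_d[s] = pre_d.get(s, 0.0) + float(w5)
                # zero-length survival: del3 exactly fills the remainder
                full_del_w += w5 * dget(m.p_del3[d], ld - d5)
        combine(pre_d, pre_ndj, float(full_del_w))

        post_v: dict = {}
        for r in range(1, len(m.p_ins_vd)):
            if m.p_ins_vd[r] > 0:
                post_v[sid(("NVD", r))] = float(m.p_ins_vd[r])
        combine(post_v, pre_d, float(m.p_ins_vd[0]))

        init: dict = {}
        for v, seq in enumerate(m.v_seqs):
            if p_v[v] == 0:
                continue
            init[sid(("V", v, 0))] = init.get(sid(("V", v, 0)), 0.0) + float(p_v[v])
            combine(init, post_v, float(p_v[v] * dget(m.p_del_v[v], len(seq))))

        # --- per-state emission and successors; creates states on demand,
        # so iterate until no new states appear
        succ: dict[int, dict] = {}
        emit: dict[int, str | None] = {}
        done = 0
        while done < len(states):
            s = done
            done += 1
            state = states[s]
            out: dict = {}
            kind = state[0]
            if kind == "V":
                _, v, k = state
                seq = m.v_seqs[v]
                emit[s] = seq[k]
                if k + 1 < len(seq):
                    out[sid(("V", v, k + 1))] = 1.0
                combine(out, post_v, dget(m.p_del_v[v], len(seq) - k - 1))
            elif kind == "NVD":
                _, r = state
                emit[s] = None
                if r > 1:
                    out[sid(("NVD", r - 1))] = 1.0
                else:
                    combine(out, pre_d, 1.0)
            elif kind == "D":
                _, d, d5, k = state
                seq = m.d_seqs[d]
                emit[s] = seq[k]
                if k + 1 < len(seq):
                    out[sid(("D", d, d5, k + 1))] = 1.0
                combine(out, pre_ndj, dget(m.p_del3[d], len(seq) - k - 1))
            elif kind == "NDJ":
                _, r = state
                emit[s] = None
                if r > 1:
                    out[sid(("NDJ", r - 1))] = 1.0
                else:
                    combine(out, pre_j, 1.0)
            elif kind == "J":
                _, j, b, t = state
                seq = m.j_seqs[j]
                emit[s] = seq[len(seq) - b + t]
                if t + 1 < b:
                    out[sid(("J", j, b, t + 1))] = 1.0
                else:
                    out[ACCEPT] = 1.0
            succ[s] = out

        n = len(states)
        self.n_states = n
        # transition matrices per emitted char: step[c][s, s'] and end weights
        self.step = {c: np.zeros((n, n)) for c in NT}
        self.end = {c: np.zeros(n) for c in NT}
        for s in range(n):
            for c in NT:
                e = m.p_nt[NT_INDEX[c]] if emit[s] is None else (1.0 if emit[s] == c else 0.0)
                if e == 0:
                    continue
                for s2, w in succ[s].items():
                    if s2 == ACCEPT:
                        self.end[c][s] += e * w
                    else:
                        self.step[c][s, s2] += e * w
        self.init = np.zeros(n)
        self.init_accept = 0.0
        for s, w in init.items():
            if s == ACCEPT:
                self.init_accept += w
            else:
                self.init[s] += w

    def forward_nt(self, seq: str) -> float:
        if not seq:
            return self.init_accept
        d = self.init
        for c in seq[:-1]:
            d = d @ self.step[c]
            if not d.any():
                return 0.0
        return float(d @ self.end[seq[-1]])

    def forward_aa(self, aa: str) -> float:
        """Forward pass branching over synonymous codons of each amino acid."""
        if not aa:
            return self.init_accept
        d = self.init
        for i, a in enumerate(aa):
            codons = CODONS_FOR_AA.get(a)
            if codons is None:
                raise ValueError(f"invalid amino acid {a!r}")
            last = i == len(aa) - 1
            acc = 0.0 if last else np.zeros_like(d)
            for codon in codons:
                t = d @ self.step[codon[0]]
                t = t @ self.step[codon[1]]
                if last:
                    acc += t @ self.end[codon[2]]
                else:
                    acc += t @ self.step[codon[2]]
            d = acc
            if last:
                return float(acc)
            if not d.any():
                return 0.0
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Public operations


def sample_rearrangement(
    model: GenerativeModel, rng_seed: int | np.random.Generator
) -> tuple[str, RecombinationScenario]:
    """Draw one junction from the generative process (reproducible by seed)."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    v = int(rng.choice(len(model.p_v), p=model.p_v))
    d = int(rng.choice(len(model.p_d), p=model.p_d))
    j = int(rng.choice(len(model.p_j), p=model.p_j))
    del_v = int(rng.choice(len(model.p_del_v[v]), p=model.p_del_v[v]))
    del5 = int(rng.choice(len(model.p_del5[d]), p=model.p_del5[d]))
    del3 = int(rng.choice(len(model.p_del3[d]), p=model.p_del3[d]))
    del_j = int(rng.choice(len(model.p_del_j[j]), p=model.p_del_j[j]))
    n_vd = int(rng.choice(len(model.p_ins_vd), p=model.p_ins_vd))
    n_dj = int(rng.choice(len(model.p_ins_dj), p=model.p_ins_dj))
    ins_vd = "".join(NT[i] for i in rng.choice(4, size=n_vd, p=model.p_nt))
    ins_dj = "".join(NT[i] for i in rng.choice(4, size=n_dj, p=model.p_nt))
    sc = RecombinationScenario(v, d, j, del_v, del5, del3, del_j, ins_vd, ins_dj)
    return sc.realize(model), sc


def sample_rearrangements(
    model: GenerativeModel, n: int, rng: int | np.random.Generator
) -> list[tuple[str, RecombinationScenario]]:
    """Vectorized batch version of :func:`sample_rearrangement`."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = model
    vs = rng.choice(len(m.p_v), size=n, p=m.p_v)
    ds = rng.choice(len(m.p_d), size=n, p=m.p_d)
    js = rng.choice(len(m.p_j), size=n, p=m.p_j)
    del_v = np.empty(n, dtype=int)
    for v in range(len(m.p_v)):
        mask = vs == v
        del_v[mask] = rng.choice(len(m.p_del_v[v]), size=int(mask.sum()), p=m.p_del_v[v])
    del5 = np.empty(n, dtype=int)
    del3 = np.empty(n, dtype=int)
    for d in range(len(m.p_d)):
        mask = ds == d
        del5[mask] = rng.choice(len(m.p_del5[d]), size=int(mask.sum()), p=m.p_del5[d])
        del3[mask] = rng.choice(len(m.p_del3[d]), size=int(mask.sum()), p=m.p_del3[d])
    del_j = np.empty(n, dtype=int)
    for j in range(len(m.p_j)):
        mask = js == j
        del_j[mask] = rng.choice(len(m.p_del_j[j]), size=int(mask.sum()), p=m.p_del_j[j])
    n_vd = rng.choice(len(m.p_ins_vd), size=n, p=m.p_ins_vd)
    n_dj = rng.choice(len(m.p_ins_dj), size=n, p=m.p_ins_dj)
    ins_chars = rng.choice(4, size=int(n_vd.sum() + n_dj.sum()), p=m.p_nt)
    ins_str = "".join(NT[i] for i in ins_chars)
    offsets = np.concatenate([[0], np.cumsum(np.concatenate([n_vd, n_dj]))])
    out = []
    for i in range(n):
        iv = ins_str[offsets[i] : offsets[i + 1]]
        ij = ins_str[offsets[n + i] : offsets[n + i + 1]]
        sc = RecombinationScenario(
            int(vs[i]), int(ds[i]), int(js[i]),
            int(del_v[i]), int(del5[i]), int(del3[i]), int(del_j[i]), iv, ij,
        )
        out.append((sc.realize(m), sc))
    return out


def pgen_nt(
    model: GenerativeModel,
    cdr3_nt: str,
    v_gene: str | None = None,
    j_gene: str | None = None,
) -> float:
    """Generation probability of a junction nucleotide string.

    Sums the probabilities of every recombination scenario realizing the
    string.  With ``v_gene``/``j_gene`` given, the sum is restricted to
    scenarios using those segments (a joint, not conditional, probability).
    """
    if set(cdr3_nt) - set(NT):
        raise ValueError(f"cdr3_nt has non-ACGT letters: {cdr3_nt!r}")
    v_idx = model.v_index(v_gene) if v_gene is not None else None
    j_idx = model.j_index(j_gene) if j_gene is not None else None
    return model.automaton(v_idx, j_idx).forward_nt(cdr3_nt)


def pgen_aa(
    model: GenerativeModel,
    cdr3_aa: str,
    v_gene: str | None = None,
    j_gene: str | None = None,
) -> float:
    """Generation probability of a CDR3 amino-acid sequence.

    Equals the sum of :func:`pgen_nt` over every nucleotide string translating
    to ``cdr3_aa``, computed by codon-level dynamic programming.
    """
    bad = [a for a in cdr3_aa if a not in CODONS_FOR_AA]
    if bad:
        raise ValueError(f"invalid amino-acid letters {bad!r}")
    v_idx = model.v_index(v_gene) if v_gene is not None else None
    j_idx = model.j_index(j_gene) if j_gene is not None else None
    return model.automaton(v_idx, j_idx).forward_aa(cdr3_aa)


def scenario_space_size(model: GenerativeModel, seq_len: int) -> int:
    """Upper bound on the number of scenario loop iterations for one string."""
    n = (
        len(model.v_seqs)
        * len(model.p_del_v[0])
        * len(model.j_seqs)
        * len(model.p_del_j[0])
        * len(model.d_seqs)
        * len(model.p_del5[0])
        * len(model.p_del3[0])
        * (seq_len + 1)
    )
    return n


def enumerate_scenarios(
    model: GenerativeModel, cdr3_nt: str, guard: int = 10_000_000
) -> list[tuple[RecombinationScenario, float]]:
    """Exhaustively list scenarios realizing ``cdr3_nt`` with probabilities.

    Test oracle for :func:`pgen_nt`; refuses models whose scenario space
    exceeds ``guard`` iterations.
    """
    size = scenario_space_size(model, len(cdr3_nt))
    if size > guard:
        raise ModelError(f"scenario space too large to enumerate (~{size} > {guard})")
    L = len(cdr3_nt)
    out: list[tuple[RecombinationScenario, float]] = []
    max_ins_vd = len(model.p_ins_vd) - 1
    max_ins_dj = len(model.p_ins_dj) - 1
    for v, vseq in enumerate(model.v_seqs):
        for del_v in range(len(model.p_del_v[v])):
            if model.p_del_v[v][del_v] == 0 or del_v > len(vseq):
                continue
            a = len(vseq) - del_v
            if a > L or cdr3_nt[:a] != vseq[: a]:
                continue
            for j, jseq in enumerate(model.j_seqs):
                for del_j in range(len(model.p_del_j[j])):
                    if model.p_del_j[j][del_j] == 0 or del_j > len(jseq):
                        continue
                    b = len(jseq) - del_j
                    if a + b > L or (b > 0 and cdr3_nt[L - b :] != jseq[del_j:]):
                        continue
                    mid = cdr3_nt[a : L - b]
                    for d, dseq in enumerate(model.d_seqs):
                        for del5 in range(len(model.p_del5[d])):
                            if model.p_del5[d][del5] == 0:
                                continue
                            for del3 in range(len(model.p_del3[d])):
                                if model.p_del3[d][del3] == 0:
                                    continue
                                if del5 + del3 > len(dseq):
                                    continue
                                core = dseq[del5 : len(dseq) - del3]
                                m_len = len(core)
                                for i in range(len(mid) - m_len + 1):
                                    if mid[i : i + m_len] != core:
                                        continue
                                    ins_vd = mid[:i]
                                    ins_dj = mid[i + m_len :]
                                    if len(ins_vd) > max_ins_vd or len(ins_dj) > max_ins_dj:
                                        continue
                                    sc = RecombinationScenario(
                                        v, d, j, del_v, del5, del3, del_j, ins_vd, ins_dj
                                    )
                                    p = sc.probability(model)
                                    if p > 0:
                                        out.append((sc, p))
    return out


def enumerate_sequence_space(
    model: GenerativeModel, guard: int = 10_000_000
) -> set[str]:
    """All nucleotide strings the model can generate (small models only)."""
    n_scen = 1
    n_scen *= sum(
        int(np.count_nonzero(model.p_del_v[v])) for v in range(len(model.v_seqs))
    )
    n_scen *= sum(
        int(np.count_nonzero(model.p_del_j[j])) for j in range(len(model.j_seqs))
    )
    n_scen *= sum(
        int(np.count_nonzero(model.p_del5[d])) * int(np.count_nonzero(model.p_del3[d]))
        for d in range(len(model.d_seqs))
    )
    ins_v = sum(4**k for k in np.nonzero(model.p_ins_vd)[0]) + (1 if model.p_ins_vd[0] > 0 else 0)
    ins_j = sum(4**k for k in np.nonzero(model.p_ins_dj)[0]) + (1 if model.p_ins_dj[0] > 0 else 0)
    n_scen *= max(ins_v, 1) * max(ins_j, 1)
    if n_scen > guard:
        raise ModelError(f"sequence space too large to enumerate (~{n_scen} scenarios)")

    def ins_strings(p_ins: np.ndarray) -> list[str]:
        out = []
        for k in np.nonzero(p_ins)[0]:
            out.extend("".join(t) for t in itertools.product(NT, repeat=int(k)))
        return out

    vd_ins = ins_strings(model.p_ins_vd)
    dj_ins = ins_strings(model.p_ins_dj)
    seqs: set[str] = set()
    for v, vseq in enumerate(model.v_seqs):
        for del_v in np.nonzero(model.p_del_v[v])[0]:
            if del_v > len(vseq):
                continue
            vpart = vseq[: len(vseq) - del_v]
            for d, dseq in enumerate(model.d_seqs):
                for del5 in np.nonzero(model.p_del5[d])[0]:
                    for del3 in np.nonzero(model.p_del3[d])[0]:
                        if del5 + del3 > len(dseq):
                            continue
                        core = dseq[del5 : len(dseq) - del3]
                        for j, jseq in enumerate(model.j_seqs):
                            for del_j in np.nonzero(model.p_del_j[j])[0]:
                                if del_j > len(jseq):
                                    continue
                                jpart = jseq[del_j:]
                                for iv in vd_ins:
                                    for ij in dj_ins:
                                        seqs.add(vpart + iv + core + ij + jpart)
    return seqs


def is_productive(cdr3_nt: str) -> bool:
    """In-frame (length divisible by 3) and free of stop codons."""
    if len(cdr3_nt) % 3 != 0 or not cdr3_nt:
        return False
    return "*" not in str(Seq(cdr3_nt).translate())


def sample_productive(
    model: GenerativeModel, n: int, rng: int | np.random.Generator
) -> list[tuple[str, str, str]]:
    """Sample ``n`` productive junctions as (v_name, j_name, cdr3_nt) triples."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[tuple[str, str, str]] = []
    while len(out) < n:
        batch = sample_rearrangements(model, max(256, int(1.3 * (n - len(out)))), rng)
        for nt, sc in batch:
            if is_productive(nt):
                out.append((model.v_names[sc.v_choice], model.j_names[sc.j_choice], nt))
                if len(out) == n:
                    break
    return out


# ---------------------------------------------------------------------------
# Shipped desk-scale models


def toy_model() -> GenerativeModel:
    """The shipped 6V/2D/4J model used throughout tests and simulations.

    Flank sequences are synthetic but follow TCR-beta conventions: V flanks
    begin at the conserved cysteine codon (TGT/TGC), J flanks end at the
    conserved phenylalanine codon (TTT/TTC), D segments are G-rich.  Flank
    interiors are pairwise >= 2 mismatches within any 6-base anchor window so
    that reference-anchored CDR3 calling is unambiguous at zero error.
    """
    return GenerativeModel(
        v_names=["TRBV19", "TRBV28", "TRBV5-1", "TRBV7-9", "TRBV6-5", "TRBV12-3"],
        v_seqs=[
            "TGTGCCAGC",  # C A S
            "TGTAGTGAA",  # C S E
            "TGTTCACGG",  # C S R
            "TGCGGGTAC",  # C G Y
            "TGTCTGTGG",  # C L W
            "TGCTACCTC",  # C Y L
        ],
        p_v=np.array([0.25, 0.20, 0.18, 0.15, 0.12, 0.10]),
        d_names=["TRBD1", "TRBD2"],
        d_seqs=["GGGACAGGGG", "GGACTAGCGGGG"],
        p_d=np.array([0.6, 0.4]),
        j_names=["TRBJ2-1", "TRBJ1-2", "TRBJ2-7", "TRBJ1-1"],
        j_seqs=[
            "AACACGTTT",  # N T F
            "GGACAGTTC",  # G Q F
            "TCCTGGTTT",  # S W F
            "CAGTACTTC",  # Q Y F
        ],
        p_j=np.array([0.30, 0.30, 0.25, 0.15]),
        p_del_v=np.tile([0.40, 0.30, 0.20, 0.10], (6, 1)),
        p_del_j=np.tile([0.40, 0.30, 0.20, 0.10], (4, 1)),
        p_del5=np.tile([0.30, 0.25, 0.20, 0.15, 0.10], (2, 1)),
        p_del3=np.tile([0.30, 0.25, 0.20, 0.15, 0.10], (2, 1)),
        p_ins_vd=np.array([0.25, 0.25, 0.20, 0.18, 0.12]),
        p_ins_dj=np.array([0.30, 0.25, 0.20, 0.15, 0.10]),
        p_nt=np.array([0.22, 0.26, 0.30, 0.22]),
    )


def tiny_model() -> GenerativeModel:
    """A 2V/1D/2J model whose full sequence space is exhaustively enumerable."""
    return GenerativeModel(
        v_names=["TRBV-a", "TRBV-b"],
        v_seqs=["TGTGCC", "TGTTCC"],
        p_v=np.array([0.6, 0.4]),
        d_names=["TRBD-a"],
        d_seqs=["GGGAC"],
        p_d=np.array([1.0]),
        j_names=["TRBJ-a", "TRBJ-b"],
        j_seqs=["AGCTTT", "AACTTC"],
        p_j=np.array([0.55, 0.45]),
        p_del_v=np.tile([0.5, 0.3, 0.2], (2, 1)),
        p_del_j=np.tile([0.5, 0.3, 0.2], (2, 1)),
        p_del5=np.array([[0.5, 0.3, 0.2]]),
        p_del3=np.array([[0.5, 0.3, 0.2]]),
        p_ins_vd=np.array([0.7, 0.3]),
        p_ins_dj=np.array([0.8, 0.2]),
        p_nt=np.array([0.3, 0.2, 0.3, 0.2]),
    )
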