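"""Minimum-free-energy folding of nucleotide windows.

Two backends behind one interface:

* ``ViennaBackend`` — adapter to the ViennaRNA (RNAfold) thermodynamic
  nearest-neighbor folder, the default for real analyses.  Folding at 37 °C,
  GU pairs allowed, and dangling-end treatment where an unpaired base joins
  at most one dangling end (ViennaRNA ``dangles=1``) — all exposed as
  configuration.
* ``SimpleNNBackend`` — a built-in simplified nearest-neighbor folder
  (pair-type stacking-energy table, hairpin loops of minimum size 3, a single
  linear penalty for bulge/interior/multibranch loops) used in unit and
  property tests.  It is a deterministic energy-minimization model in its own
  right; cross-backend tests compare each backend only against its own frozen
  fixtures.

Energies are kcal/mol, reported to 0.01; the open chain (energy 0) is always
attainable, so MFE <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_RNA_ALPHABET = frozenset("ACGU")


def to_rna(seq: str) -> str:
    """DNA -> RNA at the folding boundary (uppercase, T->U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class FoldingResult:
    delta_g: float  # kcal/mol, <= 0
    structure: str | None = None  # dot-bracket, when the backend provides one


class FoldingBackendError(RuntimeError):
    pass


def _check_sequence(seq: str) -> None:
    if len(seq) < 1:
        raise ValueError("empty sequence")
    if not set(seq) <= _RNA_ALPHABET:
        bad = sorted(set(seq) - _RNA_ALPHABET)
        raise ValueError(f"non-RNA characters in window: {bad}")


# ---------------------------------------------------------------------------
# built-in simplified nearest-neighbor folder
# ---------------------------------------------------------------------------

# base encoding A=0 C=1 G=2 U=3; pair types CG GC AU UA GU UG
_PAIR_TYPE = np.full((4, 4), -1, dtype=np.int8)
_PAIR_TYPE[1, 2] = 0
_PAIR_TYPE[2, 1] = 1
_PAIR_TYPE[0, 3] = 2
_PAIR_TYPE[3, 0] = 3
_PAIR_TYPE[2, 3] = 4
_PAIR_TYPE[3, 2] = 5

# stacking free energies (kcal/mol) by (outer, inner) pair type; magnitudes
# follow the usual nearest-neighbor ordering (GC-rich stacks strongest, GU
# weakest, two stacked GU slightly destabilizing)
_STACK = np.array(
    [
        [-3.3, -3.4, -2.4, -2.1, -1.4, -2.1],
        [-3.4, -3.3, -2.2, -2.4, -1.5, -2.5],
        [-2.4, -2.2, -0.9, -1.1, -0.6, -1.4],
        [-2.1, -2.4, -1.3, -0.9, -0.5, -1.0],
        [-1.4, -1.5, -0.5, -0.6, 0.5, -0.4],
        [-2.1, -2.5, -1.0, -1.0, -0.4, 0.5],
    ]
)

_HAIRPIN_BASE = 5.0  # closing a minimal (3-nt) hairpin loop
_HAIRPIN_PER_NT = 0.3  # linear loop-length penalty beyond 3 nt
_LOOP_PENALTY = 3.4  # single linear penalty for bulge/interior/multibranch
_MIN_HAIRPIN = 3


def _mfe_py(s: np.ndarray, pair_type: np.ndarray, stack: np.ndarray) -> float:
    n = s.shape[0]
    big = 1e9
    v = np.full((n, n), big)
    w = np.zeros((n, n))
    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            pt = pair_type[s[i], s[j]]
            if pt >= 0:
                loop = j - i - 1
                best = _HAIRPIN_BASE + _HAIRPIN_PER_NT * (loop - _MIN_HAIRPIN)
                pt2 = pair_type[s[i + 1], s[j - 1]]
                if pt2 >= 0 and v[i + 1, j - 1] < big / 2:
                    e = v[i + 1, j - 1] + stack[pt, pt2]
                    if e < best:
                        best = e
                e = w[i + 1, j - 1] + _LOOP_PENALTY
                if e < best:
                    best = e
                v[i, j] = best
            m = w[i + 1, j]
            if w[i, j - 1] < m:
                m = w[i, j - 1]
            if v[i, j] < m:
                m = v[i, j]
            for k in range(i + _MIN_HAIRPIN + 1, j - _MIN_HAIRPIN - 1):
                e = w[i, k] + w[k + 1, j]
                if e < m:
                    m = e
            if m < 0.0:
                w[i, j] = m
    return w[0, n - 1] if n > 1 else 0.0


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _mfe_kernel = njit(cache=True)(_mfe_py)
except ImportError:  # pragma: no cover
    _mfe_kernel = _mfe_py

_ENCODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGU"):
    _ENCODE[ord(_b)] = _i


class SimpleNNBackend:
    """Built-in simplified nearest-neighbor energy-minimization folder."""

    name = "simple-nn"

    def __init__(self, temperature: float = 37.0, allow_gu: bool = True,
                 dangles: int = 1):
        # temperature and dangles are accepted for interface parity; the
        # simplified energy table is defined at 37 degC and has no dangles
        self.temperature = temperature
        self.allow_gu = allow_gu
        self.dangles = dangles
        self.n_calls = 0
        pt = _PAIR_TYPE.copy()
        if not allow_gu:
            pt[2, 3] = -1
            pt[3, 2] = -1
        self._pair_type = pt

    def fold(self, seq: str) -> FoldingResult:
        _check_sequence(seq)
        self.n_calls += 1
        encoded = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        dg = float(_mfe_kernel(encoded, self._pair_type, _STACK))
        return FoldingResult(delta_g=round(dg, 2), structure=None)


class ViennaBackend:
    """Adapter to the ViennaRNA thermodynamic folder (RNAfold)."""

    name = "vienna"

    def __init__(self, temperature: float = 37.0, allow_gu: bool = True,
                 dangles: int = 1):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise FoldingBackendError(
                "ViennaRNA python bindings not available; select the "
                "'simple-nn' backend instead"
            ) from exc
        self._RNA = RNA
        md = RNA.md()
        md.temperature = temperature
        md.noGU = 0 if allow_gu else 1
        md.dangles = dangles
        self._md = md
        self.temperature = temperature
        self.allow_gu = allow_gu
        self.dangles = dangles
        self.n_calls = 0

    def fold(self, seq: str) -> FoldingResult:
        _check_sequence(seq)
        self.n_calls += 1
        fc = self._RNA.fold_compound(seq, self._md)
        structure, mfe = fc.mfe()
        # the open chain (0 kcal/mol) is always attainable
        if mfe > 0:
            return FoldingResult(delta_g=0.0, structure="." * len(seq))
        return FoldingResult(delta_g=round(float(mfe), 2), structure=structure)


_BACKENDS = {"vienna": ViennaBackend, "simple-nn": SimpleNNBackend}


def get_backend(name: str = "vienna", **kwargs) -> SimpleNNBackend | ViennaBackend:
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise FoldingBackendError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)


def fold_mfe(window_seq: str, backend) -> FoldingResult:
    """MFE of one RNA window under the given backend."""
    return backend.fold(window_seq)


def fold_batch(
    windows: Sequence[str],
    backend,
    cache: dict[str, FoldingResult] | None = None,
) -> list[FoldingResult]:
    """Order-preserving batch fold with memoization.

    Identical window strings are folded once; an external ``cache`` may be
    passed to share memoization across batches (e.g. across the permutations
    of one gene).
    """
    if cache is None:
        cache = {}
    out: list[FoldingResult] = []
    for idx, seq in enumerate(windows):
        res = cache.get(seq)
        if res is None:
            try:
                res = backend.fold(seq)
            except ValueError as exc:
                raise ValueError(f"window {idx}: {exc}") from exc
            cache[seq] = res
        out.append(res)
    return out
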