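"""Readers and writers: QAPLIB instances/solutions, matrices, result records.

QAPLIB ``.dat`` files are whitespace-separated: the size ``n`` followed by the
two n-by-n matrices row-major (line wrapping and blank lines are
insignificant).  ``.sln`` files carry ``n``, the reported objective value, and
a 1-based permutation.  Internally permutations are always 0-based; the
1-based convention appears only in ``.sln`` files and human-facing output.

The first matrix in a ``.dat`` file is ``A``, the second ``B``, and the
objective evaluated is ``trace(APB^T P^T) = sum a_uv b_{pi(u)pi(v)}``.  (A few
historical QAPLIB families swap the matrix roles; for the symmetric families
this makes no difference, and the reader does not special-case per family.)
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional
import warnings

import numpy as np

from .core import Permutation, kb_objective
from .solvers import MatchResult

__all__ = [
    "ParseError",
    "QAPLIBInstance",
    "SolutionRecord",
    "read_qaplib_dat",
    "write_qaplib_dat",
    "read_qaplib_sln",
    "write_qaplib_sln",
    "read_matrix",
    "write_matrix",
    "write_result",
    "read_result",
]

RESULT_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """A file did not match its declared format."""


@dataclass(frozen=True)
class QAPLIBInstance:
    name: str
    n: int
    A: np.ndarray  # first matrix in the file
    B: np.ndarray  # second matrix in the file


@dataclass(frozen=True)
class SolutionRecord:
    n: int
    reported_value: float
    permutation: Permutation  # 0-based

    def check(self, instance: QAPLIBInstance) -> bool:
        """Warn (and return False) if the permutation does not reproduce the value."""
        value = kb_objective(instance.A, instance.B, self.permutation)
        ok = np.isclose(value, self.reported_value, rtol=1e-9, atol=1e-6)
        if not ok:
            warnings.warn(
                f"solution permutation gives objective {value}, "
                f"file reports {self.reported_value}",
                stacklevel=2,
            )
        return bool(ok)


def _tokens(path) -> list[str]:
    return Path(path).read_text().split()


def _parse_number(tok: str, position: int, path) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric token {tok!r} at position {position}"
        ) from None


def read_qaplib_dat(path) -> QAPLIBInstance:
    """Parse a QAPLIB-format instance file (``n`` then two n^2 matrices)."""
    path = Path(path)
    toks = _tokens(path)
    if not toks:
        raise ParseError(f"{path}: empty file")
    n_f = _parse_number(toks[0], 0, path)
    n = int(n_f)
    if n != n_f or n < 1:
        raise ParseError(f"{path}: invalid size token {toks[0]!r}")
    expected = 1 + 2 * n * n
    if len(toks) != expected:
        raise ParseError(
            f"{path}: expected {expected} tokens for n = {n}, found {len(toks)}"
        )
    vals = np.array([_parse_number(t, i + 1, path) for i, t in enumerate(toks[1:])])
    A = vals[: n * n].reshape(n, n)
    B = vals[n * n:].reshape(n, n)
    # canonical QAPLIB names embed the vertex count (e.g. lipa20b -> 20)
    digits = re.findall(r"\d+", path.stem)
    if digits and int(digits[-1]) != n:
        warnings.warn(
            f"{path.stem}: size {n} does not match the numeral in the name",
            stacklevel=2,
        )
    return QAPLIBInstance(name=path.stem, n=n, A=A, B=B)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_qaplib_dat(instance: QAPLIBInstance, path) -> None:
    lines = [str(instance.n), ""]
    for M in (instance.A, instance.B):
        lines.extend(" ".join(_fmt(x) for x in row) for row in M)
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_qaplib_sln(path) -> SolutionRecord:
    """Parse a QAPLIB solution file: ``n``, objective value, 1-based permutation."""
    path = Path(path)
    toks = _tokens(path)
    if len(toks) < 2:
        raise ParseError(f"{path}: need at least n and an objective value")
    n = int(_parse_number(toks[0], 0, path))
    value = _parse_number(toks[1], 1, path)
    if len(toks) != 2 + n:
        raise ParseError(
            f"{path}: expected {2 + n} tokens for n = {n}, found {len(toks)}"
        )
    perm_1based = np.array(
        [int(_parse_number(t, i + 2, path)) for i, t in enumerate(toks[2:])]
    )
    try:
        perm = Permutation(perm_1based - 1)
    except ValueError as exc:
        raise ParseError(f"{path}: permutation is not a bijection: {exc}") from None
    return SolutionRecord(n=n, reported_value=value, permutation=perm)


def write_qaplib_sln(record: SolutionRecord, path) -> None:
    perm = " ".join(str(i + 1) for i in record.permutation.pi)
    Path(path).write_text(f"{record.n} {_fmt(record.reported_value)}\n{perm}\n")


def _read_edgelist(path, n: Optional[int], directed: bool, weighted: bool) -> np.ndarray:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{ln}: expected 'u v [w]', got {len(parts)} fields")
        u, v = int(parts[0]), int(parts[1])
        w = float(parts[2]) if len(parts) == 3 else 1.0
        if len(parts) == 3 and not weighted:
            raise ParseError(f"{path}:{ln}: weight given but weighted=False")
        if u < 0 or v < 0:
            raise ParseError(f"{path}:{ln}: negative vertex id")
        if w < 0:
            raise ParseError(f"{path}:{ln}: negative weight {w}")
        rows.append((u, v, w))
    if n is None:
        n = 1 + max((max(u, v) for u, v, _ in rows), default=-1)
    M = np.zeros((n, n))
    for u, v, w in rows:
        if u >= n or v >= n:
            raise ParseError(f"{path}: vertex id {max(u, v)} >= n = {n}")
        M[u, v] += w  # duplicates sum
        if not directed and u != v:
            M[v, u] += w
    return M


def _read_dense(path, sep_csv: bool) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    split = (lambda s: [t for t in s.split(",")]) if sep_csv else (lambda s: s.split())
    first = [t.strip() for t in split(lines[0])]
    # optional header row, auto-detected by a non-numeric first token
    try:
        float(first[0])
    except ValueError:
        lines = lines[1:]
        if not lines:
            raise ParseError(f"{path}: header but no data rows")
    data = []
    width = None
    for ln, line in enumerate(lines, start=1):
        toks = [t.strip() for t in split(line)]
        row = [_parse_number(t, i, path) for i, t in enumerate(toks)]
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(f"{path}: ragged row {ln}: {len(row)} != {width}")
        data.append(row)
    M = np.array(data)
    if M.shape[0] != M.shape[1]:
        raise ParseError(f"{path}: matrix is {M.shape[0]}x{M.shape[1]}, not square")
    return M


def read_matrix(path, format: str = "csv", n: Optional[int] = None,
                directed: bool = False, weighted: bool = True) -> np.ndarray:
    """Read a square matrix from CSV, whitespace, or (u, v[, w]) edge-list text.

    Edge lists use 0-based integer vertex ids; undirected edges are mirrored,
    duplicates sum, absent entries are 0.  CSV matrices may carry one header
    row (auto-detected by a non-numeric first token).
    """
    if format == "edgelist":
        return _read_edgelist(path, n, directed, weighted)
    if format in ("csv", "whitespace"):
        return _read_dense(path, sep_csv=(format == "csv"))
    raise ValueError(f"unknown format {format!r}")


def write_matrix(M, path, format: str = "csv") -> None:
    M = np.asarray(M)
    sep = "," if format == "csv" else " "
    if format not in ("csv", "whitespace"):
        raise ValueError(f"unknown format {format!r}")
    lines = [sep.join(_fmt(x) for x in row) for row in M]
    Path(path).write_text("\n".join(lines) + "\n")


def write_result(result: MatchResult, path) -> None:
    """Serialize a MatchResult to JSON (0-based permutation, config echo)."""
    cfg = result.config
    payload = {
        "version": RESULT_SCHEMA_VERSION,
        "permutation": [int(i) for i in result.permutation.pi],
        "objective": result.objective,
        "relaxed_objective": result.relaxed_objective,
        "n_iterations": list(result.n_iterations),
        "converged": list(result.converged),
        "restart_objectives": list(result.restart_objectives),
        "direction": result.direction.value,
        "config": {
            "seed": cfg.seed,
            "tol": cfg.tol,
            "max_iter": cfg.max_iter,
            "n_restarts": cfg.n_restarts,
            "init": cfg.init,
            "sinkhorn_iters": cfg.sinkhorn_iters,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_result(path) -> dict:
    """Load a result record written by :func:`write_result` (permutation validated)."""
    payload = json.loads(Path(path).read_text())
    Permutation(np.array(payload["permutation"]))
    return payload
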