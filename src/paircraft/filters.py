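"""Predicate-based splitting and random subsampling of pairs streams.

Filter expressions are parsed into a restricted AST (comparisons,
arithmetic, boolean logic, ``abs``, regex matching and set membership over
literals); arbitrary code execution is deliberately impossible. Callers
needing full generality can pass any Python callable as a predicate.
"""

from __future__ import annotations

import ast
import re
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .pairs_format import PairRecord

_INT_COLUMNS = {"pos1", "pos2", "mapq1", "mapq2", "score1", "score2",
                "subopt_score1", "subopt_score2", "algn_ref_span1",
                "algn_ref_span2", "walk_pair_index",
                "rfrag1_idx", "rfrag1_start", "rfrag1_end",
                "rfrag2_idx", "rfrag2_start", "rfrag2_end"}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp, ast.And, ast.Or,
    ast.UnaryOp, ast.Not, ast.USub,
    ast.BinOp, ast.Add, ast.Sub, ast.Mult,
    ast.Compare,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.In, ast.NotIn,
    ast.Name, ast.Load, ast.Constant, ast.Call,
    ast.Tuple, ast.List, ast.Set,
)
_ALLOWED_FUNCS = {"abs", "regex"}


class FilterExpressionError(ValueError):
    """Expression uses an unknown column or a disallowed construct."""


class FilterExpression:
    """A validated, compiled boolean expression over declared columns.

    Example: ``(chrom1 != chrom2) or (abs(pos1 - pos2) >= 2000)``.
    ``regex(column, pattern)`` tests a regular-expression search and
    ``column in ("a", "b")`` tests set membership.
    """

    def __init__(self, text: str, columns: Sequence[str], int_columns: set[str] | None = None):
        self.text = text
        self.columns = list(columns)
        self._int_columns = (_INT_COLUMNS if int_columns is None else int_columns)
        try:
            tree = ast.parse(text, mode="eval")
        except SyntaxError as exc:
            raise FilterExpressionError(f"cannot parse expression: {exc}") from exc
        known = set(self.columns) | {"True", "False", "None"} | _ALLOWED_FUNCS
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise FilterExpressionError(
                    f"disallowed construct {type(node).__name__} in expression"
                )
            if isinstance(node, ast.Call):
                if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
                    raise FilterExpressionError(
                        "only abs() and regex() calls are allowed"
                    )
            if isinstance(node, ast.Name) and node.id not in known:
                raise FilterExpressionError(f"unknown column {node.id!r}")
        self._code = compile(tree, "<filter>", "eval")
        self._extras_names = list(self.columns[8:])

    def _env(self, record: PairRecord) -> dict:
        env: dict = {
            "readID": record.read_id,
            "chrom1": record.chrom1,
            "pos1": record.pos1,
            "chrom2": record.chrom2,
            "pos2": record.pos2,
            "strand1": record.strand1,
            "strand2": record.strand2,
            "pair_type": record.pair_type,
        }
        for name, value in zip(self._extras_names, record.extras):
            if name in self._int_columns:
                try:
                    env[name] = int(value)
                except ValueError:
                    env[name] = value
            else:
                env[name] = value
        return env

    def __call__(self, record: PairRecord) -> bool:
        env = self._env(record)
        env["abs"] = abs
        env["regex"] = lambda s, p: re.search(p, s) is not None
        env["__builtins__"] = {}
        try:
            return bool(eval(self._code, env))
        except TypeError as exc:
            raise FilterExpressionError(
                f"type mismatch evaluating {self.text!r} on read "
                f"{record.read_id!r}: {exc}"
            ) from exc


def select(
    records: Iterable[PairRecord],
    columns: Sequence[str],
    expr: str | FilterExpression | Callable[[PairRecord], bool],
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Partition records into (matching, rest), preserving order in both."""
    if isinstance(expr, str):
        predicate: Callable[[PairRecord], bool] = FilterExpression(expr, columns)
    else:
        predicate = expr
    matching: list[PairRecord] = []
    rest: list[PairRecord] = []
    for rec in records:
        (matching if predicate(rec) else rest).append(rec)
    return matching, rest


def sample(
    records: Iterable[PairRecord],
    fraction: float | None = None,
    count: int | None = None,
    seed: int = 0,
) -> Iterator[PairRecord]:
    """Random subset of a pairs stream, deterministic given the seed.

    Fraction mode keeps each record independently with the given
    probability; count mode draws a uniform without-replacement subset of
    exact size with a single-pass reservoir. Input order is preserved.
    """
    rng = np.random.default_rng(seed)
    if (fraction is None) == (count is None):
        raise ValueError("specify exactly one of fraction or count")
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        for rec in records:
            if rng.random() < fraction:
                yield rec
        return
    reservoir: list[tuple[int, PairRecord]] = []
    n = 0
    for rec in records:
        if n < count:
            reservoir.append((n, rec))
        else:
            j = int(rng.integers(0, n + 1))
            if j < count:
                reservoir[j] = (n, rec)
        n += 1
    if count > n:
        raise ValueError(f"requested {count} records from an input of {n}")
    reservoir.sort(key=lambda kv: kv[0])
    for _, rec in reservoir:
        yield rec
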