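"""Minimal ARFF reader/writer (WEKA-compatible subset).

Supports numeric attributes plus a single trailing nominal class attribute
with values {0,1} — the shape of a descriptor learning set.  Sparse rows,
string/date attributes and quoting edge cases are out of scope.  Comment
lines (``%``) are ignored; parse errors carry 1-based line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

__all__ = ["ArffParseError", "ArffData", "read_arff", "write_arff"]


class ArffParseError(ValueError):
    """Malformed ARFF input; ``line`` is 1-based."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class ArffData:
    """Parsed ARFF content: numeric columns and an optional nominal class."""

    relation: str
    attribute_names: List[str]  # numeric attributes, in file order
    values: np.ndarray  # shape (n_rows, n_numeric)
    class_values: Optional[np.ndarray] = None  # int labels, or None
    class_attribute: Optional[str] = None
    class_domain: Optional[tuple] = None


def _strip_comment(line: str) -> str:
    # '%' starts a comment only outside quoted strings; our dialect has no
    # quoted data values, so a plain find is sufficient.
    idx = line.find("%")
    return line if idx < 0 else line[:idx]


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def read_arff(path: Union[str, Path]) -> ArffData:
    """Parse a WEKA-dialect ARFF file.

    The final attribute may be nominal (e.g. ``@attribute class {0,1}``);
    every other attribute must be numeric/real/integer.
    """
    path = Path(path)
    relation: Optional[str] = None
    names: List[str] = []
    kinds: List[str] = []  # "numeric" | "nominal"
    domains: List[Optional[tuple]] = []
    rows: List[List[str]] = []
    in_data = False
    data_start_line = -1

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = _strip_comment(raw).strip()
            if not line:
                continue
            lower = line.lower()
            if not in_data:
                if lower.startswith("@relation"):
                    relation = _unquote(line[len("@relation"):])
                elif lower.startswith("@attribute"):
                    rest = line[len("@attribute"):].strip()
                    if rest.startswith(("'", '"')):
                        quote = rest[0]
                        end = rest.index(quote, 1)
                        name = rest[1:end]
                        spec = rest[end + 1:].strip()
                    else:
                        parts = rest.split(None, 1)
                        if len(parts) != 2:
                            raise ArffParseError(
                                f"malformed @attribute: {line!r}", lineno
                            )
                        name, spec = parts
                    spec = spec.strip()
                    if spec.startswith("{"):
                        if not spec.endswith("}"):
                            raise ArffParseError(
                                f"unterminated nominal domain: {spec!r}", lineno
                            )
                        domain = tuple(
                            _unquote(v) for v in spec[1:-1].split(",") if v.strip()
                        )
                        kinds.append("nominal")
                        domains.append(domain)
                    elif spec.lower() in ("numeric", "real", "integer"):
                        kinds.append("numeric")
                        domains.append(None)
                    else:
                        raise ArffParseError(
                            f"unsupported attribute type {spec!r}", lineno
                        )
                    names.append(name)
                elif lower.startswith("@data"):
                    if relation is None:
                        raise ArffParseError("@data before @relation", lineno)
                    if not names:
                        raise ArffParseError("@data with no attributes", lineno)
                    in_data = True
                    data_start_line = lineno
                else:
                    raise ArffParseError(f"unrecognized header line: {line!r}", lineno)
            else:
                tokens = [t.strip() for t in line.split(",")]
                if len(tokens) != len(names):
                    raise ArffParseError(
                        f"expected {len(names)} values, got {len(tokens)}", lineno
                    )
                rows.append(tokens)

    if relation is None:
        raise ArffParseError("missing @relation declaration", 1)
    if not in_data:
        raise ArffParseError("missing @data section", data_start_line if data_start_line > 0 else 1)

    nominal_idx = [i for i, k in enumerate(kinds) if k == "nominal"]
    if nominal_idx and nominal_idx != [len(kinds) - 1]:
        raise ArffParseError(
            "only a single trailing nominal (class) attribute is supported", 1
        )
    has_class = bool(nominal_idx)
    n_numeric = len(names) - (1 if has_class else 0)

    values = np.empty((len(rows), n_numeric), dtype=float)
    class_vals: List[int] = []
    for r, tokens in enumerate(rows):
        for c in range(n_numeric):
            tok = tokens[c]
            if tok == "?":
                values[r, c] = np.nan
                continue
            try:
                values[r, c] = float(tok)
            except ValueError:
                raise ArffParseError(
                    f"non-numeric value {tok!r} in numeric attribute "
                    f"{names[c]!r}",
                    data_start_line + 1 + r,
                ) from None
        if has_class:
            tok = _unquote(tokens[-1])
            domain = domains[-1]
            if tok not in domain:
                raise ArffParseError(
                    f"class value {tok!r} not in domain {domain}",
                    data_start_line + 1 + r,
                )
            class_vals.append(int(tok))

    return ArffData(
        relation=relation,
        attribute_names=names[:n_numeric],
        values=values,
        class_values=np.asarray(class_vals, dtype=int) if has_class else None,
        class_attribute=names[-1] if has_class else None,
        class_domain=domains[-1] if has_class else None,
    )


def write_arff(
    path: Union[str, Path],
    relation: str,
    attribute_names: Sequence[str],
    values: np.ndarray,
    class_values: Optional[Sequence[int]] = None,
    class_attribute: str = "class",
) -> None:
    """Write a numeric matrix (plus optional {0,1} class column) as ARFF."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(attribute_names):
        raise ValueError("values shape does not match attribute_names")
    if class_values is not None and len(class_values) != values.shape[0]:
        raise ValueError("class_values length does not match row count")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in attribute_names:
            quoted = f"'{name}'" if any(ch.isspace() for ch in name) else name
            fh.write(f"@attribute {quoted} numeric\n")
        if class_values is not None:
            fh.write(f"@attribute {class_attribute} {{0,1}}\n")
        fh.write("\n@data\n")
        for r in range(values.shape[0]):
            cells = ["?" if np.isnan(v) else repr(float(v)) for v in values[r]]
            if class_values is not None:
                cells.append(str(int(class_values[r])))
            fh.write(",".join(cells) + "\n")
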