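"""MPS reading and writing.

Two dialects are supported:

* ``fixed`` — the classical commercial layout with fields at columns 2-3,
  5-12, 15-22, 25-36, 40-47 and 50-61 (1-based) and 12-character numeric
  fields;
* ``free`` — whitespace-separated tokens with the same section grammar
  (the form modern model exports use).

Parsing follows classical conventions: columns absent from BOUNDS default to
``0 <= v < +inf``; duplicate COLUMNS entries for one (row, column) pair are
summed; a range on an E row makes it two-sided.  Numeric fields are parsed at
full double precision.
"""

from __future__ import annotations

import io
import warnings

import numpy as np

from .problem import EQ, GE, LE, LPProblem, SparseMatrix


class MPSParseError(ValueError):
    def __init__(self, msg, line_no=None, line=""):
        loc = f" (line {line_no}: {line.rstrip()!r})" if line_no else ""
        super().__init__(msg + loc)


_FIXED_FIELDS = [(1, 3), (4, 12), (14, 22), (24, 36), (39, 47), (49, 61)]


def _fields_fixed(line: str) -> list[str]:
    out = []
    for a, b in _FIXED_FIELDS:
        tok = line[a:b].strip()
        if tok:
            out.append(tok)
    return out


def _num(tok: str, line_no: int, line: str) -> float:
    try:
        return float(tok.replace("D", "E").replace("d", "e"))
    except ValueError:
        raise MPSParseError(f"malformed numeric field {tok!r}", line_no, line)


def read_mps(source, dialect: str = "free") -> LPProblem:
    """Parse MPS text into an :class:`LPProblem`.

    ``source`` may be a string of MPS text, a path, or a file-like object.
    ``dialect`` is ``"fixed"`` or ``"free"``.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and len(source) < 4096:
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError:
            text = source
    else:
        text = source
    if dialect not in ("fixed", "free"):
        raise ValueError("dialect must be 'fixed' or 'free'")

    name = "LP"
    section = None
    row_names: list[str] = []
    row_sense: list[str] = []
    row_index: dict[str, int] = {}
    obj_row: str | None = None
    free_rows_ignored = 0
    col_names: list[str] = []
    col_index: dict[str, int] = {}
    entries: dict[tuple[int, int], float] = {}
    obj_coeffs: dict[int, float] = {}
    rhs: dict[int, float] = {}
    obj_rhs = 0.0
    ranges: dict[int, float] = {}
    bounds: dict[int, list] = {}     # j -> [lo, up, seen_lo, seen_up]
    saw_endata = False

    for line_no, raw in enumerate(io.StringIO(text), start=1):
        if not raw.strip() or raw.lstrip().startswith("*"):
            continue
        is_header = raw[0] not in (" ", "\t")
        if is_header:
            head = raw.split()
            keyword = head[0].upper()
            if keyword == "NAME":
                name = head[1] if len(head) > 1 else "LP"
            elif keyword == "ENDATA":
                saw_endata = True
                break
            elif keyword in ("ROWS", "COLUMNS", "RHS", "RANGES", "BOUNDS",
                             "OBJSENSE"):
                section = keyword
            else:
                raise MPSParseError(f"unknown section {keyword!r}", line_no, raw)
            continue

        toks = _fields_fixed(raw) if dialect == "fixed" else raw.split()
        if section == "OBJSENSE":
            continue  # handled below via token
        if section == "ROWS":
            if len(toks) != 2:
                raise MPSParseError("ROWS line needs sense and name", line_no, raw)
            sense, rname = toks[0].upper(), toks[1]
            if sense == "N":
                if obj_row is None:
                    obj_row = rname
                else:
                    free_rows_ignored += 1
                continue
            if sense not in (EQ, LE, GE):
                raise MPSParseError(f"unknown row sense {sense!r}", line_no, raw)
            row_index[rname] = len(row_names)
            row_names.append(rname)
            row_sense.append(sense)
        elif section == "COLUMNS":
            if len(toks) >= 3 and toks[1].upper() == "'MARKER'":
                raise MPSParseError("MILP markers are not supported", line_no, raw)
            cname = toks[0]
            if cname not in col_index:
                col_index[cname] = len(col_names)
                col_names.append(cname)
            j = col_index[cname]
            pairs = toks[1:]
            if len(pairs) % 2:
                raise MPSParseError("odd COLUMNS record", line_no, raw)
            for rname, val in zip(pairs[::2], pairs[1::2]):
                v = _num(val, line_no, raw)
                if rname == obj_row:
                    obj_coeffs[j] = obj_coeffs.get(j, 0.0) + v
                elif rname in row_index:
                    key = (row_index[rname], j)
                    entries[key] = entries.get(key, 0.0) + v
                else:
                    raise MPSParseError(f"unknown row name {rname!r} in COLUMNS",
                                        line_no, raw)
        elif section == "RHS":
            pairs = toks[1:]
            if len(pairs) % 2:
                raise MPSParseError("odd RHS record", line_no, raw)
            for rname, val in zip(pairs[::2], pairs[1::2]):
                v = _num(val, line_no, raw)
                if rname == obj_row:
                    obj_rhs = v
                elif rname in row_index:
                    rhs[row_index[rname]] = v
                else:
                    raise MPSParseError(f"unknown row name {rname!r} in RHS",
                                        line_no, raw)
        elif section == "RANGES":
            pairs = toks[1:]
            for rname, val in zip(pairs[::2], pairs[1::2]):
                if rname not in row_index:
                    raise MPSParseError(f"unknown row name {rname!r} in RANGES",
                                        line_no, raw)
                ranges[row_index[rname]] = _num(val, line_no, raw)
        elif section == "BOUNDS":
            btype = toks[0].upper()
            # free/plus/minus bound lines have no numeric field
            has_val = btype in ("LO", "UP", "FX")
            cname = toks[-2] if has_val else toks[-1]
            if cname not in col_index:
                raise MPSParseError(f"unknown column {cname!r} in BOUNDS",
                                    line_no, raw)
            j = col_index[cname]
            rec = bounds.setdefault(j, [0.0, np.inf, False, False])
            if btype in ("BV", "LI", "UI", "SC"):
                raise MPSParseError(f"integer/semicontinuous bound {btype!r} "
                                    "not supported", line_no, raw)
            if has_val:
                v = _num(toks[-1], line_no, raw)
            if btype == "LO":
                rec[0], rec[2] = v, True
            elif btype == "UP":
                rec[1], rec[3] = v, True
                # classical quirk: UP with negative value and no explicit LO
                if v < 0 and not rec[2]:
                    rec[0] = -np.inf
            elif btype == "FX":
                rec[0] = rec[1] = v
                rec[2] = rec[3] = True
            elif btype == "FR":
                rec[0], rec[1] = -np.inf, np.inf
            elif btype == "MI":
                rec[0], rec[2] = -np.inf, True
            elif btype == "PL":
                rec[1], rec[3] = np.inf, True
            else:
                raise MPSParseError(f"unknown bound type {btype!r}", line_no, raw)
        elif section is None:
            raise MPSParseError("data before any section header", line_no, raw)

    if not saw_endata:
        warnings.warn("MPS stream ended without ENDATA; accepting", stacklevel=2)
    if free_rows_ignored:
        warnings.warn(f"{free_rows_ignored} extra free (N) row(s) ignored",
                      stacklevel=2)

    m, n = len(row_names), len(col_names)
    S = SparseMatrix(m, n)
    for (i, j), v in entries.items():
        if v != 0.0:
            S.add(i, j, v)
    c = np.zeros(n)
    for j, v in obj_coeffs.items():
        c[j] = v
    b = np.zeros(m)
    for i, v in rhs.items():
        b[i] = v
    rng = np.full(m, np.nan)
    for i, v in ranges.items():
        rng[i] = v
    lo = np.zeros(n)
    up = np.full(n, np.inf)
    for j, rec in bounds.items():
        lo[j], up[j] = rec[0], rec[1]
    sense = "min"
    if "OBJSENSE" in text.upper() and "MAX" in text.upper().split("OBJSENSE")[1][:40]:
        sense = "max"
    return LPProblem(S, row_sense, b, c, lo, up, row_names, col_names, sense,
                     objective_constant=-obj_rhs,
                     ranges=rng if ranges else None, name=name)


def format_number(x: float, width: int = 12) -> str:
    """Shortest decimal representation of ``x`` fitting ``width`` characters.

    Picks the highest precision whose rendering fits; 12 characters carry
    most doubles to ~1e-10 relative accuracy and many exactly.
    """
    if x == int(x) and abs(x) < 1e11:
        s = str(int(x))
        if len(s) <= width:
            return s

    def compress(s: str) -> str:
        # classical field-squeezing: drop the leading zero of "0.xxx" and
        # zero-padding in the exponent
        if "e" in s:
            mant, exp = s.split("e")
            exp = exp.replace("+0", "+").replace("-0", "-")
            if exp.startswith("+"):
                exp = exp[1:]
            s = mant + "e" + exp
        if s.startswith("0."):
            s = s[1:]
        elif s.startswith("-0."):
            s = "-" + s[2:]
        return s

    best = None
    for prec in range(17, 0, -1):
        for s in (f"{x:.{prec}g}", compress(f"{x:.{prec}g}")):
            if len(s) <= width:
                if float(s) == x:
                    return s
                if best is None:
                    best = s
    return best if best is not None else f"{x:.5g}"


def write_mps(p: LPProblem, dialect: str = "fixed") -> str:
    """Emit MPS text that re-parses to an equivalent problem.

    In the fixed dialect numeric fields are limited to 12 characters and
    names to 8; a name collision after truncation raises.  The free dialect
    writes full-precision values (exact round trip).
    """
    if dialect not in ("fixed", "free"):
        raise ValueError("dialect must be 'fixed' or 'free'")
    width = 12 if dialect == "fixed" else 25

    def trunc(name: str) -> str:
        return name[:8] if dialect == "fixed" else name

    rnames = [trunc(r) for r in p.row_names]
    cnames = [trunc(cn) for cn in p.col_names]
    for label, names in (("row", rnames), ("column", cnames)):
        seen: dict[str, str] = {}
        collisions = []
        for orig, t in zip(p.row_names if label == "row" else p.col_names, names):
            if t in seen and seen[t] != orig:
                collisions.append(t)
            seen[t] = orig
        if collisions:
            raise ValueError(f"{label} name collision(s) after truncation: "
                             f"{sorted(set(collisions))}")
    objname = "OBJ" if "OBJ" not in set(rnames) else "OBJROW"

    def num(x: float) -> str:
        return format_number(float(x), width)

    out = [f"NAME          {p.name}"]
    if p.sense == "max":
        out.append("OBJSENSE")
        out.append("    MAX")
    out.append("ROWS")
    out.append(f" N  {objname}")
    for s, rn in zip(p.row_sense, rnames):
        sense = s if s != "R" else "G"   # explicit range rows emit as G+RANGES
        out.append(f" {sense}  {rn}")
    out.append("COLUMNS")
    cols = p.S.columns()
    for j, cn in enumerate(cnames):
        pairs = []
        if p.c[j] != 0.0:
            pairs.append((objname, p.c[j]))
        pairs.extend((rnames[i], v) for i, v in cols[j])
        if not pairs:
            pairs.append((rnames[0] if rnames else objname, 0.0))
        for k in range(0, len(pairs), 2):
            chunk = pairs[k:k + 2]
            line = f"    {cn:<8}  " + "   ".join(
                f"{rn:<8}  {num(v):<{width}}" for rn, v in chunk)
            out.append(line.rstrip())
    out.append("RHS")
    for i, rn in enumerate(rnames):
        if p.rhs[i] != 0.0:
            out.append(f"    RHS       {rn:<8}  {num(p.rhs[i])}")
    if p.objective_constant != 0.0:
        out.append(f"    RHS       {objname:<8}  {num(-p.objective_constant)}")
    if p.ranges is not None and np.any(~np.isnan(p.ranges)):
        out.append("RANGES")
        for i, rn in enumerate(rnames):
            if not np.isnan(p.ranges[i]):
                out.append(f"    RNG       {rn:<8}  {num(p.ranges[i])}")
    out.append("BOUNDS")
    for j, cn in enumerate(cnames):
        lo, up = p.lower[j], p.upper[j]
        if lo == 0.0 and np.isposinf(up):
            continue
        if lo == up:
            out.append(f" FX BND       {cn:<8}  {num(lo)}")
            continue
        if np.isneginf(lo) and np.isposinf(up):
            out.append(f" FR BND       {cn:<8}")
            continue
        if np.isneginf(lo):
            out.append(f" MI BND       {cn:<8}")
        elif lo != 0.0:
            out.append(f" LO BND       {cn:<8}  {num(lo)}")
        if not np.isposinf(up):
            out.append(f" UP BND       {cn:<8}  {num(up)}")
    out.append("ENDATA")
    return "\n".join(out) + "\n"
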