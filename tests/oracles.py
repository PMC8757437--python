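"""Independent brute-force reference computations for engine checks.

Everything here is written directly from the documented semantics with
plain python loops, deliberately not sharing code with the evaluator.
"""

import math
import re


def cmp_scalar(op, a, b):
    """Comparator semantics: int equality exact, float equality to 1e-9
    relative; strings support only =/≠."""
    if isinstance(a, str) or isinstance(b, str):
        if isinstance(a, str) and isinstance(b, str):
            return {"=": a == b, "≠": a != b}.get(op)
        return None
    if isinstance(a, int) and isinstance(b, int):
        eq = a == b
    else:
        eq = abs(a - b) <= 1e-9 * max(abs(a), abs(b))
    return {
        "<": a < b and not eq,
        "≤": a < b or eq,
        ">": a > b and not eq,
        "≥": a > b or eq,
        "=": eq,
        "≠": not eq,
    }[op]


def slice_oracle(value, op, thr):
    """Returns the filtered value, or None for an empty result."""
    if isinstance(value, dict):
        out = {k: v for k, v in value.items() if cmp_scalar(op, v, thr)}
        return out or None
    if isinstance(value, list):
        out = [v for v in value if cmp_scalar(op, v, thr)]
        return out or None
    return value if cmp_scalar(op, value, thr) else None


def reduce_oracle(name, values):
    if name == "max":
        return max(values)
    if name == "min":
        return min(values)
    if name == "sum":
        return sum(values)
    if name == "avg":
        return sum(values) / len(values)
    raise ValueError(name)


def flatten(value):
    if isinstance(value, dict):
        return list(value.values())
    if isinstance(value, list):
        return list(value)
    return [value]


def aggregate_oracle(name, per_record, group_of):
    """``per_record``: list of values (None = absent); ``group_of``: group
    key per record.  Returns the expected per-record results."""
    grouped = name in ("mmax", "mmin", "mavg", "msum")
    base = name[1:] if grouped else name
    reduced = [None if v is None else reduce_oracle(base, flatten(v)) for v in per_record]
    out = []
    for i in range(len(per_record)):
        if grouped:
            pool = [r for r, g in zip(reduced, group_of) if g == group_of[i] and r is not None]
        else:
            pool = [r for r in reduced if r is not None]
        out.append(reduce_oracle(base, pool) if pool else None)
    return out


def rank_oracle(per_record, conf_numbers, group_of):
    """1-based ascending rank within the group, ties by conformation number."""
    out = [None] * len(per_record)
    for g in set(group_of):
        idx = [
            i
            for i in range(len(per_record))
            if group_of[i] == g and per_record[i] is not None
        ]
        idx.sort(key=lambda i: (per_record[i], conf_numbers[i]))
        for rank, i in enumerate(idx, start=1):
            out[i] = rank
    return out


def elementwise_oracle(op, a, b):
    """Numeric lifting of + - * / over dict/list/scalar pairs; None on any
    failure (division by zero)."""

    def f(x, y):
        if op == "+":
            return x + y
        if op == "-":
            return x - y
        if op == "*":
            return x * y
        if y == 0:
            return None
        return x / y

    if isinstance(a, dict) and isinstance(b, dict):
        out = {}
        for k in a:
            if k in b:
                r = f(a[k], b[k])
                if r is None:
                    return None
                out[k] = r
        return out or None
    if isinstance(a, dict):
        out = {}
        for k in a:
            r = f(a[k], b)
            if r is None:
                return None
            out[k] = r
        return out
    if isinstance(b, dict):
        out = {}
        for k in b:
            r = f(a, b[k])
            if r is None:
                return None
            out[k] = r
        return out
    if isinstance(a, list) or isinstance(b, list):
        xs = a if isinstance(a, list) else [a] * len(b)
        ys = b if isinstance(b, list) else [b] * len(a)
        out = []
        for x, y in zip(xs, ys):
            r = f(x, y)
            if r is None:
                return None
            out.append(r)
        return out or None
    return f(a, b)


def regex_subtract_oracle(s, pattern):
    """Remove matches by explicit splicing (no re.sub)."""
    spans = [m.span() for m in re.finditer(pattern, s)]
    out = []
    prev = 0
    for a, b in spans:
        out.append(s[prev:a])
        prev = b
    out.append(s[prev:])
    return "".join(out)


def distances_oracle(atoms, point, ignore):
    """atoms: (index, element, x, y, z) tuples."""
    out = {}
    for idx, el, x, y, z in atoms:
        if el in ignore:
            continue
        out[idx] = math.sqrt(
            (x - point[0]) ** 2 + (y - point[1]) ** 2 + (z - point[2]) ** 2
        )
    return out or None


def hist_oracle(values, bins):
    """Equal-width binning over [min, max], right-most edge inclusive."""
    lo, hi = min(values), max(values)
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in values:
        if width == 0:
            b = 0
        else:
            b = min(int((v - lo) / width), bins - 1)
        counts[b] += 1
    return counts
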