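"""File round-tripping: case-level CSV, pattern-frequency TSV, reports.

Case-level CSV: one row per subject, k integer columns, optional header,
codes 0-based.  Pattern-frequency TSV: column 1 the comma-joined pattern
key ("0,2,1,..."), column 2 the count.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import SupportSet, ValidationError, observed_support, parse_pattern

__all__ = [
    "load_responses",
    "write_responses",
    "load_pattern_freq",
    "write_pattern_freq",
    "write_fit_json",
    "write_tests_tsv",
]


def _looks_like_header(line: str, sep: str = ",") -> bool:
    return any(not tok.strip().lstrip("-").isdigit()
               for tok in line.strip().split(sep) if tok.strip())


def load_responses(path, levels):
    """Read a case-level CSV; returns (observed SupportSet, n×k matrix)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: empty file")
    header = 0 if _looks_like_header(first) else None
    try:
        df = pd.read_csv(path, header=header, dtype=np.int64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    arr = df.to_numpy()
    return observed_support(arr, levels), arr


def write_responses(path, matrix):
    pd.DataFrame(np.asarray(matrix, dtype=np.int64)).to_csv(
        path, index=False, header=False)


def load_pattern_freq(path, levels) -> SupportSet:
    """Read a pattern-frequency TSV into a SupportSet with counts."""
    freq = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: line {ln}: expected 2 columns")
            try:
                pat = parse_pattern(parts[0])
                cnt = int(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {ln}: {exc}") from exc
            if pat in freq:
                raise ValidationError(f"{path}: line {ln}: duplicate pattern")
            freq[pat] = cnt
    pats = sorted(freq)
    return SupportSet(pats, levels, freq)


def write_pattern_freq(path, support: SupportSet):
    with open(path, "w") as fh:
        for p in support.patterns:
            cnt = (support.freq or {}).get(p, 0)
            fh.write(",".join(map(str, p)) + f"\t{cnt}\n")


def write_fit_json(path, result, extra: dict | None = None):
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_tests_tsv(path, tests: dict, seed=None):
    rows = []
    for tid, tr in tests.items():
        d = tr.to_dict()
        d["seed"] = seed
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
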