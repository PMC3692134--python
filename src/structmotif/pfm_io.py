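"""Reading and writing PFMs as JASPAR-style and TRANSFAC-like text.

JASPAR style: an optional ``>name`` header and four rows ``A [ ... ]`` in
base order A, C, G, T (bare 4-row matrices with or without brackets are
accepted, as is the transposed w x 4 layout with an ``A C G T`` header).
TRANSFAC style: ``PO  A C G T`` header, numbered position rows, ``//``
terminator.  Counts or frequencies are accepted; columns are renormalized
to frequencies on load.
"""

from __future__ import annotations

import re

import numpy as np

from .specificity import BASE_ORDER, Pfm


class PfmFormatError(ValueError):
    pass


def _normalize(matrix: np.ndarray, support: int = 0) -> Pfm:
    sums = matrix.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise PfmFormatError("a PFM position has zero total count")
    return Pfm(matrix / sums, support=support)


def write_jaspar(pfm: Pfm, name: str = "motif") -> str:
    lines = [f">{name}"]
    for i, base in enumerate(BASE_ORDER):
        vals = " ".join(f"{v:.6f}" for v in pfm.frequencies[:, i])
        lines.append(f"{base} [ {vals} ]")
    return "\n".join(lines) + "\n"


def write_transfac(pfm: Pfm, name: str = "motif") -> str:
    lines = [f"ID {name}", "PO\tA\tC\tG\tT"]
    for j in range(pfm.width):
        vals = "\t".join(f"{v:.6f}" for v in pfm.frequencies[j])
        lines.append(f"{j + 1:02d}\t{vals}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def read_pfm(text: str) -> Pfm:
    """Parse a PFM from JASPAR-style, TRANSFAC-like, or bare matrix text."""
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    if not lines:
        raise PfmFormatError("empty PFM text")
    if any(l.upper().startswith("PO") for l in lines):
        return _read_transfac(lines)
    return _read_jaspar(lines)


def _read_transfac(lines: list[str]) -> Pfm:
    header_idx = next(i for i, l in enumerate(lines)
                      if l.upper().startswith("PO"))
    cols = lines[header_idx].split()[1:]
    if [c.upper() for c in cols] != list(BASE_ORDER):
        raise PfmFormatError(f"unsupported TRANSFAC base order {cols}")
    rows = []
    for l in lines[header_idx + 1:]:
        if l.startswith("//") or l.upper().startswith(("XX", "CC", "ID")):
            continue
        parts = l.split()
        if len(parts) < 5:
            raise PfmFormatError(f"unreadable TRANSFAC row: {l!r}")
        rows.append([float(x) for x in parts[1:5]])
    if not rows:
        raise PfmFormatError("TRANSFAC matrix has no position rows")
    return _normalize(np.array(rows))


def _read_jaspar(lines: list[str]) -> Pfm:
    lines = [l for l in lines if not l.startswith((">", "#"))]
    rows = []
    labels = []
    for l in lines:
        m = re.match(r"^([ACGTacgt])\s*[:\[]?\s*(.*?)\]?\s*$", l)
        if m and not re.fullmatch(r"[\d.eE+\-\s]*", l):
            labels.append(m.group(1).upper())
            body = m.group(2).replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
        else:
            rows.append([float(x) for x in l.replace("[", " ")
                        .replace("]", " ").split()])
    mat = np.array(rows, dtype=float)
    if labels:
        if labels == list(BASE_ORDER) and len(rows) == 4:
            mat = mat.T                      # 4 x w labelled rows
        else:
            raise PfmFormatError(f"unsupported base-row order {labels}")
    elif mat.ndim == 2 and mat.shape[0] == 4 and mat.shape[1] != 4:
        mat = mat.T                          # bare 4 x w matrix
    elif mat.ndim != 2 or mat.shape[1] != 4:
        raise PfmFormatError(f"cannot interpret matrix of shape {mat.shape}")
    return _normalize(mat)
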