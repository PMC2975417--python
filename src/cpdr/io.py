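"""Shared plain-text I/O for cluster-like vertex sets.

Format: one set per line, members tab-separated and sorted; lines sorted by
the canonical clique ordering (size descending, then lexicographic).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable, TextIO, Union

from .cliques import clique_sort_key

Sink = Union[str, Path, TextIO]


def write_text_atomic(path: str | Path, text: str) -> None:
    """Write via a sibling temp file and rename, so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_vertex_sets(sets: Iterable[frozenset[str]], sink: Sink) -> None:
    ordered = sorted((frozenset(s) for s in sets), key=clique_sort_key)
    lines = ["\t".join(sorted(s)) for s in ordered]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, (str, Path)):
        write_text_atomic(sink, text)
    else:
        sink.write(text)


def read_vertex_sets(source: Sink) -> list[frozenset[str]]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(frozenset(tok for tok in line.split("\t") if tok))
    return out
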