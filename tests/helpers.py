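"""Shared test utilities: random tree generation and small builders."""

from __future__ import annotations

import random
import string

from phyloconcord.supermatrix import LocusAlignment
from phyloconcord.trees_io import parse_newick


def labels(n: int) -> list[str]:
    """n short labels: a, b, c, ..."""
    assert n <= 26
    return list(string.ascii_lowercase[:n])


def random_binary_newick(leaf_labels: list[str], rnd: random.Random,
                         lengths: bool = False) -> str:
    """Random rooted binary topology by repeated random joins."""
    parts = list(leaf_labels)
    if lengths:
        parts = [f"{p}:{rnd.uniform(0.1, 2.0):.4f}" for p in parts]
    while len(parts) > 1:
        i, j = sorted(rnd.sample(range(len(parts)), 2))
        b = parts.pop(j)
        a = parts.pop(i)
        joined = f"({a},{b})"
        if lengths:
            joined += f":{rnd.uniform(0.1, 2.0):.4f}"
        parts.append(joined)
    root = parts[0]
    if lengths:  # the final join's length would be a root edge; drop it
        root = root[:root.rfind(":")]
    return root + ";"


def random_binary_tree(leaf_labels: list[str], rnd: random.Random,
                       lengths: bool = False):
    return parse_newick(random_binary_newick(leaf_labels, rnd, lengths))


def locus(locus_id: str, seqs: dict[str, str]) -> LocusAlignment:
    return LocusAlignment(locus_id=locus_id, sequences=seqs)
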