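"""Sequence grammar analysis: trie, pattern classes, combinatorial rules.

A call sequence is a string over the alphabet {A, B} of length >= 2.  The
corpus-level analysis asks three questions: which exact strings occur and how
often (the trie and the "sequence type" tally), which of four regular pattern
classes each string belongs to, and whether three combinatorial rules hold:

* A-Dominance   — B calls never outnumber A calls (#B <= #A);
* A-Suffixation — every sequence ends with an A call;
* B-Singularity — B calls are never adjacent ("BB" never occurs).

The four pattern classes (A-repetition ``A{2,}``, ``(BA)+``, ``A+(BA)+`` and
``(BA)+A+``) are mutually exclusive, and every string in one of them obeys all
three rules; the converse fails (e.g. "ABAA" is rule-conforming but belongs to
no class).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

ALPHABET = frozenset("AB")
RULES = ("A_dominance", "A_suffixation", "B_singularity")
PATTERN_LABELS = ("A_repeat", "BA", "A_BA", "BA_A", "other")

_PATTERN_RE = (
    ("A_repeat", re.compile(r"A{2,}\Z")),
    ("BA", re.compile(r"(?:BA)+\Z")),
    ("A_BA", re.compile(r"A+(?:BA)+\Z")),
    ("BA_A", re.compile(r"(?:BA)+A+\Z")),
)


def _validate(symbols: str) -> None:
    if len(symbols) < 2:
        raise ValueError(f"sequence {symbols!r} shorter than 2 calls")
    if not ALPHABET.issuperset(symbols):
        raise ValueError(f"sequence {symbols!r} contains symbols outside A/B")


def classify_pattern(symbols: str) -> str:
    """Pattern class of a full sequence string; "other" if none matches."""
    _validate(symbols)
    for label, rx in _PATTERN_RE:
        if rx.match(symbols):
            return label
    return "other"


def rule_predicates(symbols: str) -> dict[str, bool]:
    """Evaluate the three combinatorial rules on one sequence string."""
    _validate(symbols)
    n_a = symbols.count("A")
    return {
        "A_dominance": 2 * n_a >= len(symbols),
        "A_suffixation": symbols[-1] == "A",
        "B_singularity": "BB" not in symbols,
    }


@dataclass
class RuleReport:
    holds: dict[str, bool]
    violating_ids: dict[str, list[int]]
    violation_fraction: dict[str, float]
    n_sequences: int


def check_rules(sequences: Iterable[str]) -> RuleReport:
    """Evaluate all three rules over a corpus of sequence strings."""
    seqs = list(sequences)
    viol: dict[str, list[int]] = {r: [] for r in RULES}
    for i, s in enumerate(seqs):
        preds = rule_predicates(s)
        for r in RULES:
            if not preds[r]:
                viol[r].append(i)
    n = len(seqs)
    frac = {r: (len(viol[r]) / n if n else 0.0) for r in RULES}
    return RuleReport(
        holds={r: not viol[r] for r in RULES},
        violating_ids=viol,
        violation_fraction=frac,
        n_sequences=n,
    )


def bigram_counts(symbols: str) -> dict[str, int]:
    """Counts of the n-1 contiguous call pairs of one sequence."""
    _validate(symbols)
    counts = {"AA": 0, "AB": 0, "BA": 0, "BB": 0}
    for a, b in zip(symbols, symbols[1:]):
        counts[a + b] += 1
    return counts


def initiation(symbols: str) -> str:
    """First call of the sequence ("A" or "B")."""
    _validate(symbols)
    return symbols[0]


def termination_bigram(symbols: str) -> str:
    """Terminal bigram class: "AA_gram", "BA_gram" or "other".

    Rule-conforming corpora only ever terminate in AA- or BA-grams; the
    "other" class exists for robustness to corrupted input.
    """
    _validate(symbols)
    last = symbols[-2:]
    return {"AA": "AA_gram", "BA": "BA_gram"}.get(last, "other")


# ---------------------------------------------------------------------------
# trie


@dataclass
class TrieNode:
    """Prefix-tree node; ``terminal_count`` is the end-of-sequence marker
    tally and ``pass_count`` the number of sequences through the node."""

    symbol: str  # "root", "A" or "B"
    depth: int = 0
    children: dict[str, "TrieNode"] = field(default_factory=dict)
    terminal_count: int = 0
    pass_count: int = 0

    def walk(self):
        yield self
        for sym in sorted(self.children):
            yield from self.children[sym].walk()

    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())


def build_trie(sequences: Iterable[str]) -> TrieNode:
    """Aggregate a corpus of sequence strings into a prefix trie.

    Conservation law at every node: terminal_count + sum of child pass
    counts = pass_count.  Total terminal count over the trie equals the
    corpus size.
    """
    root = TrieNode("root", 0)
    for s in sequences:
        _validate(s)
        root.pass_count += 1
        node = root
        for sym in s:
            if sym not in node.children:
                node.children[sym] = TrieNode(sym, node.depth + 1)
            node = node.children[sym]
            node.pass_count += 1
        node.terminal_count += 1
    return root


def export_trie_dot(trie: TrieNode, path=None) -> str:
    """Render the trie as a Graphviz DOT digraph.

    Call nodes are labeled by symbol; each sequence ending is drawn as an
    edge to a terminal marker node labeled with the count.  Depth is used
    as rank.  Returns the DOT source; writes it to ``path`` when given.
    """
    lines = ["digraph trie {", "  rankdir=LR;", '  node [shape=circle];']
    ids: dict[int, str] = {}
    ranks: dict[int, list[str]] = {}
    for i, node in enumerate(trie.walk()):
        nid = f"n{i}"
        ids[id(node)] = nid
        label = node.symbol if node.symbol != "root" else "root"
        shape = "box" if node.symbol == "root" else "circle"
        lines.append(f'  {nid} [label="{label}", shape={shape}];')
        ranks.setdefault(node.depth, []).append(nid)
    term = 0
    for i, node in enumerate(trie.walk()):
        nid = ids[id(node)]
        for sym in sorted(node.children):
            lines.append(f"  {nid} -> {ids[id(node.children[sym])]};")
        if node.terminal_count > 0:
            tid = f"t{term}"
            term += 1
            lines.append(
                f'  {tid} [label="{node.terminal_count}", shape=plaintext];')
            lines.append(f'  {nid} -> {tid} [label="end"];')
    for depth in sorted(ranks):
        lines.append("  { rank=same; " + "; ".join(ranks[depth]) + "; }")
    lines.append("}")
    dot = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(dot)
    return dot


# ---------------------------------------------------------------------------
# corpus summary


def repertoire_summary(sequences: Iterable[str]) -> dict:
    """Corpus-level tallies over sequence strings.

    "Sequence type" means exact string identity; "pattern" means the regex
    class.  Shares are percentages of the number of sequences.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty corpus")
    for s in seqs:
        _validate(s)
    n = len(seqs)
    lengths = np.array([len(s) for s in seqs])
    from collections import Counter

    types = Counter(seqs)
    mixed = sum(1 for s in seqs if "B" in s and "A" in s)
    a_rep = sum(1 for s in seqs if set(s) == {"A"})
    b_rep = sum(1 for s in seqs if set(s) == {"B"})
    pat = Counter(classify_pattern(s) for s in seqs)
    init = Counter(initiation(s) for s in seqs)
    term = Counter(termination_bigram(s) for s in seqs)
    pct = lambda c: 100.0 * c / n
    return {
        "n_sequences": n,
        "n_types": len(types),
        "n_singleton_types": sum(1 for c in types.values() if c == 1),
        "mean_length": float(lengths.mean()),
        "sd_length": float(lengths.std(ddof=1)) if n > 1 else 0.0,
        "max_length": int(lengths.max()),
        "pct_mixed": pct(mixed),
        "pct_A_repetition": pct(a_rep),
        "pct_B_repetition": pct(b_rep),
        "pattern_pct": {p: pct(pat.get(p, 0)) for p in PATTERN_LABELS},
        "initiation_pct": {s: pct(init.get(s, 0)) for s in ("A", "B")},
        "termination_pct": {t: pct(term.get(t, 0))
                            for t in ("AA_gram", "BA_gram", "other")},
    }
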