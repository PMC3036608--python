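from __future__ import annotations

from pathlib import Path

import pytest

from phytoscan.motif import IUPAC_SETS, DegeneratePattern, compile_pattern


@pytest.fixture
def p1bs() -> DegeneratePattern:
    return compile_pattern("GNATATNC")


@pytest.fixture
def write_fasta(tmp_path: Path):
    def _write(entries: list[tuple[str, str]], name: str = "test.fasta") -> Path:
        path = tmp_path / name
        with path.open("w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; they never share code with
# the scanning implementation under test)


def naive_scan(seq: str, pattern: DegeneratePattern, strands: str = "both"):
    """Window-by-window set-membership scan; mirrors the published contract:
    1-based offsets, reverse hits read on their own strand, exact-window
    dedup reported as '±' with the forward read."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    k = pattern.k
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        fwd = all(b in s for b, s in zip(window, pattern.position_sets))
        if strands == "forward":
            if fwd:
                out.append((i + 1, "+", window))
            continue
        rc_window = "".join(comp[b] for b in reversed(window))
        rev = all(b in s for b, s in zip(rc_window, pattern.position_sets))
        if fwd and rev:
            out.append((i + 1, "±", window))
        elif fwd:
            out.append((i + 1, "+", window))
        elif rev:
            out.append((i + 1, "-", rc_window))
    return out


def exact_hit_probability(pattern: DegeneratePattern, length: int) -> float:
    """Exact P(>=1 match on the forward strand) for an i.i.d. uniform
    sequence, by dynamic programming over active-prefix bitmask states."""
    k = pattern.k
    sets = pattern.position_sets
    # state: frozenset of active prefix lengths (1..k-1); match absorbs
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def step(state: frozenset, base: str):
        nxt = set()
        matched = False
        for ln in list(state) + [0]:
            if base in sets[ln]:
                if ln + 1 == k:
                    matched = True
                else:
                    nxt.add(ln + 1)
        return frozenset(nxt), matched

    probs = {frozenset(): 1.0}
    p_match = 0.0
    for _ in range(length):
        new: dict = {}
        for state, p in probs.items():
            for base in "ACGT":
                nxt, matched = step(state, base)
                q = p * 0.25
                if matched:
                    p_match += q
                else:
                    new[nxt] = new.get(nxt, 0.0) + q
        probs = new
    return p_match


def random_iupac_text(rng, k: int) -> str:
    codes = sorted(IUPAC_SETS)
    return "".join(rng.choice(codes) for _ in range(k))
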