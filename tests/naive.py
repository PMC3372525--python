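"""Brute-force reference implementations used as independent oracles.

Everything here is written with plain nested loops and no shared code with
the package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

GAP, MASK = "-", "X"
AA = "ACDEFGHIKLMNPQRSTVWY"


def _real(c: str) -> bool:
    return c != GAP and c != MASK


def naive_identity(msa: dict[str, str], species: str, column: int) -> float:
    mine = msa[species][column]
    matches = total = 0
    for sp, seq in msa.items():
        if sp == species or not _real(seq[column]):
            continue
        total += 1
        if seq[column] == mine:
            matches += 1
    return matches / total if total else 0.0


def naive_mask(
    msa: dict[str, str],
    window: int = 10,
    min_divergent: int = 4,
    threshold: float = 0.30,
    min_run: int = 10,
) -> dict[str, str]:
    out = {}
    for sp, seq in msa.items():
        positions = [i for i, c in enumerate(seq) if _real(c)]
        qualifying = []
        for i in range(len(positions) - window + 1):
            n_div = 0
            for j in range(i, i + window):
                if naive_identity(msa, sp, positions[j]) < threshold:
                    n_div += 1
            if n_div >= min_divergent:
                qualifying.append(i)
        masked_real: set[int] = set()
        for i in qualifying:
            for j in range(i, i + window):
                masked_real.add(j)
        is_div = [
            naive_identity(msa, sp, p) < threshold for p in positions
        ]
        chars = list(seq)
        runs: list[list[int]] = []
        run: list[int] = []
        for j in sorted(masked_real) + [-99]:
            if run and j != run[-1] + 1:
                runs.append(run)
                run = []
            run.append(j)
        for run in runs:
            div = [j for j in run if is_div[j]]
            if not div:
                continue
            trimmed = range(div[0], div[-1] + 1)
            if len(trimmed) < min_run:
                continue
            for r in trimmed:
                chars[positions[r]] = MASK
        out[sp] = "".join(chars)
    return out


def naive_classify(
    msa: dict[str, str],
    reference: str,
    required: list[str],
    min_chars: int = 10,
    min_diff: int = 3,
) -> list[str]:
    length = len(next(iter(msa.values())))
    classes = []
    for col in range(length):
        chars = {sp: seq[col] for sp, seq in msa.items() if _real(seq[col])}
        if (
            len(chars) < min_chars
            or reference not in chars
            or any(sp not in chars for sp in required)
        ):
            classes.append("excluded")
            continue
        ref_res = chars[reference]
        n_diff = sum(1 for sp, c in chars.items() if sp != reference and c != ref_res)
        classes.append("fit" if n_diff >= min_diff else "conserved")
    return classes


def naive_pearson_chisq(observed, expected) -> float:
    stat = 0.0
    for o, e in zip(observed, expected):
        stat += (o - e) ** 2 / e
    return stat


def random_toy_msa(rng: np.random.Generator) -> dict[str, str]:
    """A small random alignment mixing conserved, noisy and divergent
    columns, with gaps, for oracle-agreement tests."""
    n_sp = int(rng.integers(8, 13))
    length = int(rng.integers(25, 46))
    species = [f"s{i}" for i in range(n_sp)]
    cols = []
    for _ in range(length):
        style = rng.random()
        if style < 0.5:  # conserved
            cols.append([AA[rng.integers(20)]] * n_sp)
        elif style < 0.8:  # a few variants
            base = AA[rng.integers(20)]
            cols.append(
                [base if rng.random() < 0.7 else AA[rng.integers(20)]
                 for _ in range(n_sp)]
            )
        else:  # scattered
            cols.append([AA[rng.integers(20)] for _ in range(n_sp)])
    # sprinkle gaps
    for i in range(n_sp):
        for j in range(length):
            if rng.random() < 0.05:
                cols[j][i] = GAP
    # sometimes implant a long divergent segment in one species
    if rng.random() < 0.6:
        victim = int(rng.integers(n_sp))
        start = int(rng.integers(0, max(1, length - 16)))
        for j in range(start, min(length, start + int(rng.integers(8, 18)))):
            cols[j][victim] = AA[rng.integers(20)]
    return {
        sp: "".join(cols[j][i] for j in range(length))
        for i, sp in enumerate(species)
    }
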