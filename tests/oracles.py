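"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: an elemental
mass table typed in from published isotope masses (slightly different
literals than the package's), quadratic-time peak matching, exhaustive
FDR threshold sweeps, and ladder comparisons by double loop. These stay
independent of the code paths they check.
"""

from __future__ import annotations

import itertools

# Published monoisotopic atomic masses, independent literals.
ORACLE_ELEMENTS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207069,
}

ORACLE_RESIDUE_FORMULAS = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

ORACLE_PROTON = 1.007276466879
ORACLE_WATER = 2 * ORACLE_ELEMENTS["H"] + ORACLE_ELEMENTS["O"]


def oracle_residue_mass(residue: str) -> float:
    return sum(
        ORACLE_ELEMENTS[el] * n for el, n in ORACLE_RESIDUE_FORMULAS[residue].items()
    )


def oracle_neutral_mass(sequence: str, deltas=()) -> float:
    """Peptide neutral mass from the oracle's own atomic masses."""
    return sum(oracle_residue_mass(r) for r in sequence) + ORACLE_WATER + sum(deltas)


def oracle_fragment_mzs(sequence: str, mods: dict, charge: int = 1) -> dict:
    """(series, index) -> m/z using plain prefix/suffix sums."""
    site_masses = [
        oracle_residue_mass(r) + mods.get(i + 1, 0.0)
        for i, r in enumerate(sequence)
    ]
    out = {}
    n = len(sequence)
    for i in range(1, n):
        b = sum(site_masses[:i])
        y = sum(site_masses[n - i :]) + ORACLE_WATER
        out[("b", i)] = (b + charge * ORACLE_PROTON) / charge
        out[("y", i)] = (y + charge * ORACLE_PROTON) / charge
    return out


def brute_force_fic(theoretical, peak_mzs, tol_ppm: float) -> float:
    """All-pairs tolerance scan over (series,index,charge,mz) fragments."""
    positions = {(series, index) for series, index, _, _ in theoretical}
    matched = set()
    for series, index, _, mz in theoretical:
        for peak in peak_mzs:
            if abs(peak - mz) / mz * 1e6 <= tol_ppm:
                matched.add((series, index))
                break
    return len(matched) / len(positions)


def brute_force_fdr_threshold(targets, decoys, level):
    """Exhaustive sweep over all distinct scores; smallest passing score.

    A score passes if some threshold at or below it has decoy/target
    ratio <= level (the q-value construction, done the slow way).
    """
    distinct = sorted(set(targets) | set(decoys))

    def fdr(s):
        n_t = sum(1 for t in targets if t >= s)
        n_d = sum(1 for d in decoys if d >= s)
        if n_d == 0:
            return 0.0
        if n_t == 0:
            return float("inf")
        return n_d / n_t

    passing = [
        s
        for s in distinct
        if min(fdr(t) for t in distinct if t <= s) <= level
    ]
    return min(passing) if passing else None


def brute_force_site_determining(ladder_a: dict, ladder_b: dict, tol_ppm: float):
    """Unique/shared partition by exhaustive cross-ladder comparison."""
    def unique(own, other):
        out = set()
        for pos, mz in own.items():
            if not any(abs(mz - o) / o * 1e6 <= tol_ppm for o in other.values()):
                out.add(pos)
        return out

    ua = unique(ladder_a, ladder_b)
    ub = unique(ladder_b, ladder_a)
    shared = set(ladder_a) - ua - ub
    return ua, ub, shared


def brute_force_enumerate_count(n_sites: int, max_background: int) -> int:
    """Number of subsets of eligible sites with size <= max_background."""
    return sum(
        1
        for r in range(n_sites + 1)
        for _ in itertools.combinations(range(n_sites), r)
        if r <= max_background
    )
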