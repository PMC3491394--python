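"""Design of binding-site-abolishing mutations.

Up to five substitutions are chosen greedily to minimize the site's PWM
match (uniform-background log-odds, for reproducibility), while vetoing
any substitution that would create a match to another factor's consensus
pattern anywhere in the local sequence context, on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .motif_core import PWM, BASES, information_content, log_odds_score, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ConsensusLibrary:
    """Known consensus binding patterns, as (tf name, IUPAC pattern) pairs."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for tf, pattern in self.entries:
            if len(pattern) < 4:
                raise ValueError(f"pattern for {tf} shorter than 4")
            for ch in pattern.upper():
                if ch not in IUPAC:
                    raise ValueError(f"invalid IUPAC code {ch!r} in pattern for {tf}")

    def without(self, tf_name: str) -> "ConsensusLibrary":
        """Drop a factor's own entries (its original site trivially matches)."""
        return ConsensusLibrary(tuple(e for e in self.entries if e[0] != tf_name))

    @property
    def max_pattern_length(self) -> int:
        return max((len(p) for _, p in self.entries), default=0)


@dataclass(frozen=True)
class MutationPlan:
    original: str
    mutated: str
    positions: tuple[int, ...]
    score_before: float
    score_after: float
    exhausted: bool = False  # set when no admissible substitution remained

    def __post_init__(self):
        diffs = tuple(i for i, (a, b) in enumerate(zip(self.original, self.mutated)) if a != b)
        if diffs != tuple(sorted(self.positions)):
            raise ValueError("positions inconsistent with original/mutated diff")
        if self.score_after > self.score_before + 1e-12:
            raise ValueError("mutation must not increase the PWM score")


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[ch]}]" for ch in pattern.upper()))


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff the IUPAC pattern occurs at any offset on either strand of seq."""
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r}")
    rx = _pattern_regex(pattern)
    seq = seq.upper()
    return bool(rx.search(seq) or rx.search(reverse_complement(seq)))


def _matches_library(seq_in_context: str, library: ConsensusLibrary) -> bool:
    return any(iupac_match(seq_in_context, pattern) for _, pattern in library.entries)


def design_mutation(
    site: str,
    pwm: PWM,
    library: ConsensusLibrary = ConsensusLibrary(()),
    left_flank: str = "",
    right_flank: str = "",
    max_mut: int = 5,
) -> MutationPlan:
    """Greedy site-abolishing mutation design.

    Each round considers every single substitution at a not-yet-mutated
    position, scores the mutated site against the PWM (uniform background)
    and picks the admissible substitution with the lowest score.  A
    substitution is inadmissible if the flanks + mutated site would match
    any library pattern on either strand.  Ties break toward the position
    with higher information content, then leftmost, then alphabetical base.
    Stops early once the minimum achievable score is reached; if a round has
    no admissible substitution, the plan so far is returned with
    ``exhausted=True``.
    """
    site = site.upper()
    if len(site) != pwm.width:
        raise ValueError(f"site length {len(site)} != PWM width {pwm.width}")
    ic = information_content(pwm)
    logf = np.log2(np.maximum(pwm.frequencies, 1e-300)) - np.log2(0.25)
    min_achievable = float(logf.min(axis=1).sum())

    current = list(site)
    used: list[int] = []
    score_before = log_odds_score(pwm, site)
    score = score_before

    for _ in range(max_mut):
        if score <= min_achievable + 1e-12:
            break
        best = None  # (score, -ic, pos, base)
        for pos in range(pwm.width):
            if pos in used:
                continue
            for base in BASES:
                if base == current[pos]:
                    continue
                trial = current.copy()
                trial[pos] = base
                trial_seq = "".join(trial)
                cand_score = log_odds_score(pwm, trial_seq)
                key = (cand_score, -ic[pos], pos, base)
                if best is not None and key >= best:
                    continue
                if _matches_library(left_flank + trial_seq + right_flank, library):
                    continue
                best = key
        if best is None:
            return MutationPlan(
                site, "".join(current), tuple(sorted(used)),
                score_before, score, exhausted=True,
            )
        cand_score, _, pos, base = best
        if cand_score > score:  # cannot lower the score further this round
            break
        current[pos] = base
        used.append(pos)
        score = cand_score

    return MutationPlan(site, "".join(current), tuple(sorted(used)), score_before, score)


def plans_to_tsv(plans: dict[str, MutationPlan], path) -> None:
    """Write plans keyed by site id as TSV."""
    import pandas as pd

    rows = [
        (
            site_id, p.original, p.mutated, ",".join(map(str, p.positions)),
            p.score_before, p.score_after, p.exhausted,
        )
        for site_id, p in plans.items()
    ]
    pd.DataFrame(
        rows,
        columns=["site_id", "original", "mutated", "positions",
                 "score_before", "score_after", "flag"],
    ).to_csv(path, sep="\t", index=False)
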