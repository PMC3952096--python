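"""Evolutionary-trace conservation scores.

The Evolutionary Trace (ET) method ranks residues by sequence conservation
across homologs; a low rank means a low mutation rate, i.e. high
conservation. The per-residue conservation score standardizes the rank
against its chain:

    c_i = (mu - rank_i) / sigma

with mu and sigma the mean and standard deviation of the chain's ET ranks,
so c_i is a z-score with the sign flipped: positive = more conserved than the
chain average. A residue is conservation-critical when c_i is strictly
positive (threshold configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

__all__ = [
    "ConservationProfile",
    "ConservationError",
    "parse_et_ranks",
    "conservation_scores",
    "conservation_critical",
    "profile_to_tsv",
]


class ConservationError(ValueError):
    pass


@dataclass
class ConservationProfile:
    chain: str
    ranks: Dict[int, float]      # residue number -> ET rank
    scores: Dict[int, float]     # residue number -> c_i
    mu: float
    sigma: float


def parse_et_ranks(text: str, dialect: str = "et_server") -> Dict[int, float]:
    """Parse an ET rank file into {residue number: rank}.

    ``et_server``: '%'-comment header lines are skipped; data lines carry
    whitespace-delimited columns (alignment#, residue#, residue type, rank,
    ...). ``tsv``: two tab-separated columns, residue number and rank.
    Duplicate residue numbers are an error.
    """
    if dialect not in ("et_server", "tsv"):
        raise ConservationError(f"unknown dialect {dialect!r}")
    if not text.strip():
        raise ConservationError("empty rank file")
    ranks: Dict[int, float] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if dialect == "et_server":
            if stripped.startswith("%") or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise ConservationError(
                    f"line {ln}: expected >=4 columns "
                    "(alignment#, residue#, type, rank)")
            try:
                resnum = int(parts[1])
                rank = float(parts[3])
            except ValueError as exc:
                raise ConservationError(f"line {ln}: {exc}") from None
        else:
            if stripped.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConservationError(
                    f"line {ln}: expected residue_number<TAB>rank")
            try:
                resnum = int(parts[0])
                rank = float(parts[1])
            except ValueError as exc:
                raise ConservationError(f"line {ln}: {exc}") from None
        if resnum in ranks:
            raise ConservationError(f"line {ln}: duplicate residue {resnum}")
        ranks[resnum] = rank
    if not ranks:
        raise ConservationError("no data rows in rank file")
    return ranks


def conservation_scores(ranks: Dict[int, float], sigma_mode: str = "population",
                        chain: str = "A") -> ConservationProfile:
    """Compute c_i = (mu - rank_i) / sigma over one chain's ranks."""
    if len(ranks) < 2:
        raise ConservationError("need at least 2 ranked residues")
    if sigma_mode not in ("population", "sample"):
        raise ConservationError(f"unknown sigma_mode {sigma_mode!r}")
    values = list(ranks.values())
    n = len(values)
    mu = sum(values) / n
    ss = sum((v - mu) ** 2 for v in values)
    denom = n if sigma_mode == "population" else n - 1
    sigma = math.sqrt(ss / denom)
    if sigma == 0.0:
        raise ConservationError(
            "all ranks identical (sigma = 0); conservation criticality "
            "is undefined for this chain")
    scores = {res: (mu - r) / sigma for res, r in ranks.items()}
    return ConservationProfile(chain=chain, ranks=dict(ranks),
                               scores=scores, mu=mu, sigma=sigma)


def conservation_critical(profile: ConservationProfile,
                          tau_c: float = 0.0) -> Dict[int, bool]:
    """Flag residues with conservation score strictly above ``tau_c``."""
    return {res: c > tau_c for res, c in profile.scores.items()}


def profile_to_tsv(profile: ConservationProfile, tau_c: float = 0.0) -> str:
    flags = conservation_critical(profile, tau_c)
    lines = ["chain\tresnum\trank\tc_i\tcritical"]
    for res in sorted(profile.ranks):
        lines.append(f"{profile.chain}\t{res}\t{profile.ranks[res]:g}\t"
                     f"{profile.scores[res]:.6f}\t{flags[res]}")
    return "\n".join(lines) + "\n"
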