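"""Combining conservation and rigidity verdicts, and confusion analysis
against experimental stability (ddG) data.

Per residue the two boolean detections (conservation-critical, rigidity-
critical) combine into four agreement categories and an OR-based
``combined_detected`` flag. Where an experimental ddG of unfolding is known,
a residue counts as experimentally critical when its ddG falls in a
destabilizing window (default -10 <= ddG < 0 kcal/mol), and each record
receives a TP/FP/TN/FN confusion label. Per-protein summaries report the
category percentages; cohort summaries average them across proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Tuple

__all__ = [
    "DdgRecord",
    "ResidueVerdict",
    "ProteinSummary",
    "ReportError",
    "combine_verdicts",
    "experimental_criticality",
    "confusion_vs_experiment",
    "protein_summary",
    "cohort_summary",
    "binding_site_crosscount",
    "parse_ddg_tsv",
    "verdicts_to_tsv",
]

CATEGORIES = ("both_critical", "both_noncritical", "cons_only", "rig_only")


class ReportError(ValueError):
    pass


@dataclass
class DdgRecord:
    pdb_id: str
    wt_residue: str          # one-letter wild-type code
    position: int
    mutant: str              # one-letter mutant code, G or A in scope
    ddg: float               # kcal/mol; negative = destabilizing
    sasa: Optional[float] = None
    binding_partners: Optional[int] = None

    def __post_init__(self):
        if self.position < 1:
            raise ReportError(f"position must be >= 1 (got {self.position})")
        if self.binding_partners is not None and self.binding_partners < 0:
            raise ReportError("binding_partners must be >= 0")

    @property
    def mutation(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mutant}"


@dataclass
class ResidueVerdict:
    residue_key: tuple
    cons_critical: bool
    rig_critical: bool
    category: str
    combined_detected: bool
    confusion: Optional[str] = None   # TP / FP / TN / FN
    cons_score: Optional[float] = None
    pct_decrease: Optional[float] = None

    def __post_init__(self):
        expected = _category(self.cons_critical, self.rig_critical)
        if self.category != expected:
            raise ReportError(f"category {self.category!r} inconsistent with flags")
        if self.combined_detected != (self.cons_critical or self.rig_critical):
            raise ReportError("combined_detected must be the OR of the two flags")


@dataclass
class ProteinSummary:
    pdb_id: str
    n_residues: int
    pct_cons_critical: float
    pct_rig_critical: float
    pct_both_critical: float
    pct_both_noncritical: float
    pct_total_match: float
    pct_cons_only: float
    pct_rig_only: float


def _category(cons: bool, rig: bool) -> str:
    if cons and rig:
        return "both_critical"
    if cons:
        return "cons_only"
    if rig:
        return "rig_only"
    return "both_noncritical"


def round1(x: float) -> float:
    """Half-up rounding to one decimal (matching printed table digits)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def combine_verdicts(cons_flags: Dict, rig_flags: Dict,
                     cons_scores: Optional[Dict] = None,
                     pct_decreases: Optional[Dict] = None) -> List[ResidueVerdict]:
    """Join the two per-residue flag maps into verdicts.

    Residues present in only one map are reported (warning) and excluded; an
    empty intersection is an error.
    """
    import warnings

    common = sorted(set(cons_flags) & set(rig_flags),
                    key=lambda k: (str(k[0]), k[1], k[2]) if isinstance(k, tuple) else k)
    if not common:
        raise ReportError("conservation and rigidity maps share no residues")
    only = set(cons_flags) ^ set(rig_flags)
    if only:
        warnings.warn(f"{len(only)} residues present in only one map were excluded: "
                      f"{sorted(map(str, only))[:10]}")
    out = []
    for key in common:
        cons = bool(cons_flags[key])
        rig = bool(rig_flags[key])
        out.append(ResidueVerdict(
            residue_key=key,
            cons_critical=cons,
            rig_critical=rig,
            category=_category(cons, rig),
            combined_detected=cons or rig,
            cons_score=(cons_scores or {}).get(key),
            pct_decrease=(pct_decreases or {}).get(key),
        ))
    return out


def experimental_criticality(record: DdgRecord,
                             window: Tuple[float, float] = (-10.0, 0.0)) -> bool:
    """Experimentally critical iff lo <= ddG < hi (hi exclusive)."""
    lo, hi = window
    return lo <= record.ddg < hi


def confusion_vs_experiment(verdicts: List[ResidueVerdict],
                            records: List[DdgRecord],
                            window: Tuple[float, float] = (-10.0, 0.0),
                            wt_types: Optional[Dict] = None) -> Dict[str, int]:
    """Attach TP/FP/TN/FN labels to verdicts with a matching ddG record.

    Records are matched to verdicts by residue position (and wild-type
    residue identity when ``wt_types`` maps residue keys to one-letter
    codes). Returns the confusion counts.
    """
    by_pos: Dict[int, ResidueVerdict] = {}
    for v in verdicts:
        pos = v.residue_key[1] if isinstance(v.residue_key, tuple) else v.residue_key
        by_pos[pos] = v
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for rec in records:
        v = by_pos.get(rec.position)
        if v is None:
            continue
        if wt_types is not None:
            wt = wt_types.get(v.residue_key)
            if wt is not None and wt != rec.wt_residue:
                raise ReportError(
                    f"wild-type mismatch at position {rec.position}: structure "
                    f"has {wt}, record says {rec.wt_residue}")
        critical = experimental_criticality(rec, window)
        if critical and v.combined_detected:
            label = "TP"
        elif critical:
            label = "FN"
        elif v.combined_detected:
            label = "FP"
        else:
            label = "TN"
        v.confusion = label
        counts[label] += 1
    return counts


def protein_summary(verdicts: List[ResidueVerdict], pdb_id: str) -> ProteinSummary:
    """Category percentages over the protein's residues, half-up one decimal."""
    if not verdicts:
        raise ReportError("no verdicts to summarize")
    n = len(verdicts)
    cat = {c: 0 for c in CATEGORIES}
    for v in verdicts:
        cat[v.category] += 1
    pct = {c: 100.0 * k / n for c, k in cat.items()}
    return ProteinSummary(
        pdb_id=pdb_id,
        n_residues=n,
        pct_cons_critical=round1(pct["both_critical"] + pct["cons_only"]),
        pct_rig_critical=round1(pct["both_critical"] + pct["rig_only"]),
        pct_both_critical=round1(pct["both_critical"]),
        pct_both_noncritical=round1(pct["both_noncritical"]),
        pct_total_match=round1(pct["both_critical"] + pct["both_noncritical"]),
        pct_cons_only=round1(pct["cons_only"]),
        pct_rig_only=round1(pct["rig_only"]),
    )


_SUMMARY_COLUMNS = ("pct_cons_critical", "pct_rig_critical", "pct_both_critical",
                    "pct_both_noncritical", "pct_total_match", "pct_cons_only",
                    "pct_rig_only")


def cohort_summary(rows: List[ProteinSummary]) -> Dict[str, float]:
    """Unweighted arithmetic mean of each percentage column, one decimal."""
    if not rows:
        raise ReportError("no protein summaries")
    out = {}
    for col in _SUMMARY_COLUMNS:
        out[col] = round1(sum(getattr(r, col) for r in rows) / len(rows))
    return out


def binding_site_crosscount(records: List[DdgRecord],
                            ddg_max: float = -1.0,
                            sasa_min: float = 0.0) -> Tuple[int, int]:
    """Count solvent-accessible strongly destabilized residues, and how many
    of those have at least one known binding partner.

    A record qualifies with ddG < ``ddg_max``, SASA > ``sasa_min`` and the
    two optional annotation columns present. Reported for orientation only;
    the tally depends on the exact SASA/ddG cutoffs chosen.
    """
    accessible = [r for r in records
                  if r.sasa is not None and r.ddg < ddg_max and r.sasa > sasa_min]
    with_partner = [r for r in accessible
                    if r.binding_partners is not None and r.binding_partners >= 1]
    return len(accessible), len(with_partner)


# ---------------------------------------------------------------------------
# I/O

def parse_ddg_tsv(text: str) -> List[DdgRecord]:
    """ddG table TSV with header: pdb, wt, pos, mut, ddg[, sasa, partners]."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ReportError("empty ddG table")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = ("pdb", "wt", "pos", "mut", "ddg")
    for col in required:
        if col not in header:
            raise ReportError(f"ddG table missing column {col!r}")
    idx = {h: i for i, h in enumerate(header)}
    records = []
    for ln, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        try:
            rec = DdgRecord(
                pdb_id=parts[idx["pdb"]],
                wt_residue=parts[idx["wt"]],
                position=int(parts[idx["pos"]]),
                mutant=parts[idx["mut"]],
                ddg=float(parts[idx["ddg"]]),
                sasa=float(parts[idx["sasa"]]) if "sasa" in idx
                     and parts[idx["sasa"]] != "" else None,
                binding_partners=int(parts[idx["partners"]]) if "partners" in idx
                     and parts[idx["partners"]] != "" else None,
            )
        except (ValueError, IndexError) as exc:
            raise ReportError(f"ddG table line {ln}: {exc}") from None
        records.append(rec)
    return records


def verdicts_to_tsv(verdicts: List[ResidueVerdict]) -> str:
    lines = ["chain\tresnum\ticode\tcons_score\tpct_decrease\tcons_critical\t"
             "rig_critical\tcategory\tcombined_detected\tconfusion"]
    for v in verdicts:
        key = v.residue_key
        cid, num, icode = key if isinstance(key, tuple) else ("", key, "")
        cs = f"{v.cons_score:.4f}" if v.cons_score is not None else ""
        pd = f"{v.pct_decrease:.4f}" if v.pct_decrease is not None else ""
        lines.append(f"{cid}\t{num}\t{icode}\t{cs}\t{pd}\t{v.cons_critical}\t"
                     f"{v.rig_critical}\t{v.category}\t{v.combined_detected}\t"
                     f"{v.confusion or ''}")
    return "\n".join(lines) + "\n"
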