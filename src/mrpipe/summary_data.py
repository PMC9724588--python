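"""Reading, selection, and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization starts from per-SNP association
summaries (beta, SE, p, allele labels, allele frequency) for an exposure
and an outcome measured in non-overlapping cohorts.  This module turns
raw delimited tables into analysis-ready instrument sets:

* validation of per-SNP records,
* p-value instrument selection (genome-wide significance by default),
* greedy LD clumping against a pairwise r² table,
* allele harmonization across traits (sign flips, palindrome removal,
  outcome-significance exclusion, optional proxy substitution),
* instrument-strength diagnostics (per-SNP F, variance explained R²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mrpipe")

VALID_ALLELES = frozenset("ACGT")

#: default header names -> record roles for delimited GWAS tables
DEFAULT_COLUMN_MAP = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

REQUIRED_ROLES = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


class MRError(RuntimeError):
    """Fatal pipeline error (bad input, too few instruments, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for one trait.

    ``beta`` is per effect-allele copy, in SD units for continuous traits
    and log-odds for binary traits; ``se`` is its standard error.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: int = 0

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is valid."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive se"
        if not math.isfinite(self.beta):
            return "nonfinite beta"
        if not (0 < self.pval <= 1):
            return "pval outside (0,1]"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf outside [0,1]"
        return None


@dataclass
class LDTable:
    """Symmetric pairwise r² lookup keyed on rsID pairs."""

    _r2: dict[frozenset, float] = field(default_factory=dict)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 {r2} outside [0,1]")
        self._r2[frozenset((snp_a, snp_b))] = r2

    def get(self, snp_a: str, snp_b: str) -> float | None:
        """r² for the pair, 1.0 for a SNP with itself, None if absent."""
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)))

    def partners(self, snp_id: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for pair, r2 in self._r2.items():
            if snp_id in pair:
                others = pair - {snp_id}
                if others:
                    out[next(iter(others))] = r2
        return out

    @classmethod
    def from_file(cls, path) -> "LDTable":
        df = pd.read_csv(path, sep=None, engine="python")
        table = cls()
        for a, b, r2 in df.itertuples(index=False):
            table.add(str(a), str(b), float(r2))
        return table


@dataclass
class InstrumentSet:
    """Instruments selected for one exposure (possibly pre-clumping)."""

    exposure_name: str
    records: list[GwasRecord]
    selection_pvalue: float
    clump_r2: float | None = None
    clump_window_bp: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


@dataclass
class HarmonizedSet:
    """Allele-aligned effect/SE matrices across one outcome and >=1 exposures.

    Row j of every array refers to ``snp_ids[j]``; effects are oriented to
    the primary (first) exposure's effect allele.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    beta_exp: np.ndarray  # (J, K)
    se_exp: np.ndarray  # (J, K)
    beta_out: np.ndarray  # (J,)
    se_out: np.ndarray  # (J,)
    eaf: np.ndarray  # (J,) primary-exposure EAF, nan when missing
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposure(self) -> int:
        return self.beta_exp.shape[1]

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            exposure_names=list(self.exposure_names),
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            eaf=self.eaf[idx],
            exclusions=list(self.exclusions),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"snp_id": self.snp_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.beta_exp[:, k]
            data[f"se_{name}"] = self.se_exp[:, k]
        data["beta_outcome"] = self.beta_out
        data["se_outcome"] = self.se_out
        data["eaf"] = self.eaf
        return pd.DataFrame(data)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["snp_id", "reason"])


@dataclass
class StrengthSummary:
    """Instrument-strength diagnostics for one exposure."""

    per_snp_f: np.ndarray
    mean_f: float
    min_f: float
    median_f: float
    total_r2: float
    n_snp: int
    n_missing_eaf: int = 0

    def to_dict(self) -> dict:
        return {
            "n_snp": self.n_snp,
            "mean_f": self.mean_f,
            "min_f": self.min_f,
            "median_f": self.median_f,
            "total_r2": self.total_r2,
            "n_missing_eaf": self.n_missing_eaf,
        }


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_gwas_table(
    path, column_map: dict[str, str] | None = None
) -> tuple[list[GwasRecord], list[tuple[str, str]]]:
    """Read a delimited GWAS summary table into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping from header names to record roles; must cover at least
        snp_id, effect_allele, other_allele, beta, se, pval.  Defaults to
        the SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N dialect.

    Returns
    -------
    (records, rejections)
        Valid records, and (snp_id, reason) pairs for dropped rows.

    Raises
    ------
    MRError
        If the file is unreadable, a required column is missing, or no
        valid rows remain.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise MRError(f"cannot read GWAS table {path}: {exc}") from exc

    roles = {role: col for col, role in column_map.items() if col in df.columns}
    missing = [r for r in REQUIRED_ROLES if r not in roles]
    if missing:
        raise MRError(f"GWAS table {path} missing required columns for roles: {missing}")

    records: list[GwasRecord] = []
    rejections: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        snp = str(row[roles["snp_id"]])
        try:
            rec = GwasRecord(
                snp_id=snp,
                chrom=str(row[roles["chrom"]]) if "chrom" in roles else "",
                pos=int(float(row[roles["pos"]])) if "pos" in roles else 0,
                effect_allele=str(row[roles["effect_allele"]]).upper(),
                other_allele=str(row[roles["other_allele"]]).upper(),
                eaf=_opt_float(row.get(roles.get("eaf"))),
                beta=float(row[roles["beta"]]),
                se=float(row[roles["se"]]),
                pval=float(row[roles["pval"]]),
                n=int(float(row[roles["n"]])) if "n" in roles and not _is_na(row[roles["n"]]) else 0,
            )
        except (TypeError, ValueError):
            rejections.append((snp, "unparseable row"))
            continue
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            rejections.append((snp, reason))
    if not records:
        raise MRError(f"GWAS table {path}: zero valid rows")
    if rejections:
        logger.warning("%s: dropped %d invalid rows", path, len(rejections))
    return records, rejections


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or (
        isinstance(x, str) and x.strip() in ("", "NA", "nan", "NaN")
    )


def _opt_float(x) -> float | None:
    if _is_na(x):
        return None
    return float(x)


def write_gwas_table(records: list[GwasRecord], path) -> None:
    """Write records in the default SNP/CHR/POS/... dialect (tab-delimited)."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf if r.eaf is not None else "NA" for r in records],
            "BETA": [repr(r.beta) for r in records],
            "SE": [repr(r.se) for r in records],
            "P": [repr(r.pval) for r in records],
            "N": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# selection and clumping
# ---------------------------------------------------------------------------


def select_instruments(
    records: list[GwasRecord], p_threshold: float, exposure_name: str = "exposure"
) -> InstrumentSet:
    """Keep records with association p-value strictly below ``p_threshold``.

    Genome-wide significance (5e-8) is the conventional threshold; traits
    with few hits may use a relaxed one (e.g. 1e-5).
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold {p_threshold} outside (0,1)")
    kept = [r for r in records if r.pval < p_threshold]
    if not kept:
        raise MRError(
            f"no instruments for {exposure_name} at p < {p_threshold:g}"
        )
    return InstrumentSet(exposure_name, kept, p_threshold)


def clump(
    instruments: InstrumentSet,
    ld: LDTable | None,
    r2_max: float = 0.001,
    window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Greedy LD clumping: keep approximately independent instruments.

    Candidates are visited in order of ascending p-value (ties broken by
    rsID).  A SNP is accepted unless it lies within ``window_bp`` of an
    already-accepted SNP on the same chromosome and either their r² in
    ``ld`` is >= ``r2_max`` or the pair is absent from ``ld`` — absent
    within-window pairs are treated as dependent, the conservative choice
    when no full LD reference panel is available.
    """
    if not instruments.records:
        raise MRError("clump: empty instrument set")
    if not (0 < r2_max < 1):
        raise ValueError(f"r2_max {r2_max} outside (0,1)")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    ld = ld or LDTable()
    ordered = sorted(instruments.records, key=lambda r: (r.pval, r.snp_id))
    accepted: list[GwasRecord] = []
    for cand in ordered:
        dependent = False
        for acc in accepted:
            if cand.chrom != acc.chrom:
                continue
            if abs(cand.pos - acc.pos) > window_bp:
                continue
            r2 = ld.get(cand.snp_id, acc.snp_id)
            if r2 is None or r2 >= r2_max:
                dependent = True
                break
        if not dependent:
            accepted.append(cand)
    accepted.sort(key=lambda r: (r.pval, r.snp_id))
    return InstrumentSet(
        instruments.exposure_name,
        accepted,
        instruments.selection_pvalue,
        clump_r2=r2_max,
        clump_window_bp=window_bp,
    )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous A/T or C/G pairs (either order)."""
    pair = frozenset((effect_allele.upper(), other_allele.upper()))
    return pair == frozenset("AT") or pair == frozenset("CG")


def find_proxy(
    snp_id: str,
    outcome_snp_ids,
    ld: LDTable,
    min_r2: float = 0.8,
) -> str | None:
    """Best outcome-present proxy for a SNP missing from the outcome table.

    Returns the outcome SNP with the highest r² to ``snp_id`` among those
    with r² strictly above ``min_r2``; ties broken by lexicographic rsID.
    """
    outcome_ids = set(outcome_snp_ids)
    best: tuple[float, str] | None = None
    for partner, r2 in ld.partners(snp_id).items():
        if partner not in outcome_ids or r2 <= min_r2:
            continue
        # prefer higher r2; on ties the lexicographically smaller rsID
        if best is None or r2 > best[0] or (r2 == best[0] and partner < best[1]):
            best = (r2, partner)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _align(target: GwasRecord, ref_ea: str, ref_oa: str) -> GwasRecord | None:
    """Orient ``target`` to the reference effect allele, or None on mismatch."""
    if target.effect_allele == ref_ea and target.other_allele == ref_oa:
        return target
    if target.effect_allele == ref_oa and target.other_allele == ref_ea:
        return replace(
            target,
            effect_allele=ref_ea,
            other_allele=ref_oa,
            beta=-target.beta,
            eaf=None if target.eaf is None else 1.0 - target.eaf,
        )
    return None


def harmonize(
    exposures: InstrumentSet | list[InstrumentSet],
    outcome: list[GwasRecord],
    outcome_sig_threshold: float = 5e-8,
    ld: LDTable | None = None,
    use_proxies: bool = False,
    min_proxy_r2: float = 0.8,
    min_snps: int | None = None,
) -> HarmonizedSet:
    """Align one or more exposure instrument sets with an outcome table.

    Walks the primary (first) exposure's instruments in order and, per SNP:

    * drops palindromic (A/T, C/G) variants — strand unresolvable;
    * requires the SNP in every co-exposure table, aligning betas to the
      primary effect allele (sign flip + EAF complement on swapped labels);
    * requires the SNP in the outcome table, substituting a proxy with
      r² > ``min_proxy_r2`` when ``use_proxies`` and an LD table is given;
    * drops SNPs whose outcome association p-value is below
      ``outcome_sig_threshold`` (they may act directly on the outcome,
      violating the exclusion restriction); pass 0.0 to disable.

    Every dropped SNP is logged with exactly one reason code, so input
    SNP counts are conserved between the harmonized set and the log.
    """
    if isinstance(exposures, InstrumentSet):
        exposures = [exposures]
    if not exposures or not exposures[0].records:
        raise MRError("harmonize: primary exposure set is empty")
    primary = exposures[0]
    k = len(exposures)
    co_lookup = [{r.snp_id: r for r in ex.records} for ex in exposures[1:]]
    out_lookup = {r.snp_id: r for r in outcome}

    snp_ids: list[str] = []
    beta_exp: list[list[float]] = []
    se_exp: list[list[float]] = []
    beta_out: list[float] = []
    se_out: list[float] = []
    eafs: list[float] = []
    exclusions: list[tuple[str, str]] = []

    seen: set[str] = set()
    for rec in primary.records:
        if rec.snp_id in seen:
            exclusions.append((rec.snp_id, "duplicate"))
            continue
        seen.add(rec.snp_id)
        if is_palindromic(rec.effect_allele, rec.other_allele):
            exclusions.append((rec.snp_id, "palindromic"))
            continue
        # canonical orientation (alphabetical effect allele) so the result is
        # invariant to how the input happens to label effect/other alleles
        if rec.effect_allele > rec.other_allele:
            rec = replace(
                rec,
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
                beta=-rec.beta,
                eaf=None if rec.eaf is None else 1.0 - rec.eaf,
            )

        row_b = [rec.beta]
        row_s = [rec.se]
        missing_co = None
        for name_idx, lookup in enumerate(co_lookup):
            co = lookup.get(rec.snp_id)
            co = _align(co, rec.effect_allele, rec.other_allele) if co else None
            if co is None:
                missing_co = exposures[name_idx + 1].exposure_name
                break
            row_b.append(co.beta)
            row_s.append(co.se)
        if missing_co is not None:
            exclusions.append((rec.snp_id, f"missing-in-exposure:{missing_co}"))
            continue

        out_rec = out_lookup.get(rec.snp_id)
        if out_rec is None and use_proxies and ld is not None:
            proxy_id = find_proxy(rec.snp_id, out_lookup.keys(), ld, min_proxy_r2)
            if proxy_id is not None:
                out_rec = out_lookup[proxy_id]
                exclusions.append((rec.snp_id, f"proxy-substituted:{proxy_id}"))
        if out_rec is None:
            exclusions.append((rec.snp_id, "missing-in-outcome"))
            continue
        if out_rec.snp_id == rec.snp_id:
            out_rec = _align(out_rec, rec.effect_allele, rec.other_allele)
            if out_rec is None:
                exclusions.append((rec.snp_id, "allele-mismatch"))
                continue
        if outcome_sig_threshold > 0 and out_rec.pval < outcome_sig_threshold:
            exclusions.append((rec.snp_id, "outcome-significant"))
            continue

        snp_ids.append(rec.snp_id)
        beta_exp.append(row_b)
        se_exp.append(row_s)
        beta_out.append(out_rec.beta)
        se_out.append(out_rec.se)
        eafs.append(rec.eaf if rec.eaf is not None else np.nan)

    required = min_snps if min_snps is not None else (3 if k == 1 else k + 2)
    if len(snp_ids) < required:
        raise MRError(
            f"harmonize: only {len(snp_ids)} SNPs survive, need >= {required} "
            f"for {k} exposure(s)"
        )
    h = HarmonizedSet(
        snp_ids=snp_ids,
        exposure_names=[ex.exposure_name for ex in exposures],
        beta_exp=np.asarray(beta_exp, dtype=float).reshape(len(snp_ids), k),
        se_exp=np.asarray(se_exp, dtype=float).reshape(len(snp_ids), k),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out, dtype=float),
        eaf=np.asarray(eafs, dtype=float),
        exclusions=exclusions,
    )
    return h


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument F statistic, beta²/se²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def variance_explained(eaf: float | None, beta: float) -> float | None:
    """Exposure variance explained by one SNP: 2·EAF·(1−EAF)·beta².

    Assumes the exposure is on the SD scale and the SNP genotype is in
    Hardy–Weinberg equilibrium.  Returns None when EAF is missing.
    """
    if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)):
        return None
    if not (0 <= eaf <= 1):
        raise ValueError(f"eaf {eaf} outside [0,1]")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def strength_summary(instruments: InstrumentSet) -> StrengthSummary:
    """Aggregate instrument strength: mean/min/median F and total R².

    Emits a weak-instrument warning when mean F < 10 (the conventional
    bar below which two-sample MR estimates attenuate toward the null).
    SNPs without EAF contribute to F but are excluded from total R²
    with a warning.
    """
    if not instruments.records:
        raise MRError("strength_summary: empty instrument set")
    fs = np.array([f_statistic(r.beta, r.se) for r in instruments.records])
    r2s = [variance_explained(r.eaf, r.beta) for r in instruments.records]
    n_missing = sum(1 for v in r2s if v is None)
    if n_missing:
        logger.warning(
            "%s: %d SNP(s) lack EAF; excluded from total R2",
            instruments.exposure_name,
            n_missing,
        )
    total_r2 = float(sum(v for v in r2s if v is not None))
    mean_f = float(fs.mean())
    if mean_f < 10:
        logger.warning(
            "%s: mean F %.2f < 10 — possible weak-instrument bias",
            instruments.exposure_name,
            mean_f,
        )
    return StrengthSummary(
        per_snp_f=fs,
        mean_f=mean_f,
        min_f=float(fs.min()),
        median_f=float(np.median(fs)),
        total_r2=total_r2,
        n_snp=len(fs),
        n_missing_eaf=n_missing,
    )
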