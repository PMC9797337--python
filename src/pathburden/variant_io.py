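"""Read annotated multi-sample VCFs and apply the qualifying-variant filter.

A *qualifying variant* is a putative loss-of-function allele — stop-gain,
start-loss, frameshift insertion/deletion, or canonical splice-site
disruption — that is rare in a large reference population (at most 10
alternate alleles per 280,000 reference chromosomes, a gnomAD-style
count cutoff).  Every multi-allelic site is decomposed into one record
per ALT allele before the filter is applied, so allele counts and
consequence classes are always per-ALT.

Three annotation dialects are supported:

``info_tags``
    flat INFO fields ``GENE``, ``CSQ_CLASS``, ``POP_AC``, ``POP_AN``
    (comma-separated per ALT where multi-allelic);
``vep_csq``
    the VEP ``CSQ`` INFO string, field layout taken from the header
    ``Description`` line (``Allele``, ``Consequence``, ``SYMBOL`` plus
    optional ``gnomAD_AC``/``gnomAD_AN`` columns);
``snpeff_ann``
    the SnpEff ``ANN`` INFO string (allele, annotation, impact,
    gene name, ...), with population counts from ``POP_AC``/``POP_AN``
    INFO tags when present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "CONSEQUENCE_CLASSES",
    "DEFAULT_CONSEQUENCE_MAP",
    "VariantRecord",
    "QualifyingFilter",
    "VcfFormatError",
    "classify_consequence",
    "load_consequence_map",
    "read_vcf",
    "is_qualifying",
]

#: sentinel dosage for an uncalled genotype
MISSING = -1

CONSEQUENCE_CLASSES = (
    "stop_gain",
    "start_loss",
    "frameshift_insertion",
    "frameshift_deletion",
    "canonical_splice",
    "other",
)

# Sequence-Ontology term -> internal consequence class.  ``frameshift``
# entries are disambiguated to insertion/deletion by REF/ALT lengths at
# classification time.  Extended splice-region terms deliberately map to
# ``other``: only the +/-1-2 bp donor/acceptor dinucleotides count as
# canonical splice disruption.
DEFAULT_CONSEQUENCE_MAP: dict[str, str] = {
    "stop_gained": "stop_gain",
    "stop_gain": "stop_gain",
    "start_lost": "start_loss",
    "start_loss": "start_loss",
    "initiator_codon_variant": "start_loss",
    "frameshift_variant": "frameshift",
    "frameshift": "frameshift",
    "frameshift_insertion": "frameshift_insertion",
    "frameshift_deletion": "frameshift_deletion",
    "splice_acceptor_variant": "canonical_splice",
    "splice_donor_variant": "canonical_splice",
    "canonical_splice": "canonical_splice",
}


class VcfFormatError(ValueError):
    """Malformed or under-annotated VCF content."""


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele at one site, with annotation and genotype dosages.

    ``genotypes`` maps sample ID to the count of *this* ALT allele in the
    called genotype (0, 1 or 2), or :data:`MISSING` for uncalled.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_allele_count: int
    pop_allele_number: int
    genotypes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if self.pop_allele_number <= 0:
            raise ValueError("pop_allele_number must be positive")
        if not 0 <= self.pop_allele_count <= self.pop_allele_number:
            raise ValueError(
                f"pop_allele_count {self.pop_allele_count} outside "
                f"[0, {self.pop_allele_number}]"
            )


@dataclass(frozen=True)
class QualifyingFilter:
    """Pure predicate selecting rare loss-of-function variants.

    Rarity is a count cutoff expressed against a reference denominator:
    at most ``max_pop_allele_count`` ALT alleles in
    ``reference_allele_number`` chromosomes.  Records annotated against a
    different denominator are judged on the frequency scale,
    ``AC/AN <= max_count/reference_AN``, so cohorts annotated with
    different reference releases remain comparable.  The boundary is
    inclusive.
    """

    allowed_consequences: frozenset[str] = frozenset(
        c for c in CONSEQUENCE_CLASSES if c != "other"
    )
    max_pop_allele_count: int = 10
    reference_allele_number: int = 280_000

    def __post_init__(self) -> None:
        if self.max_pop_allele_count < 0:
            raise ValueError("max_pop_allele_count must be >= 0")
        if self.reference_allele_number <= 0:
            raise ValueError("reference_allele_number must be > 0")
        unknown = set(self.allowed_consequences) - set(CONSEQUENCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
        # dataclass(frozen) + mutable default guard
        object.__setattr__(
            self, "allowed_consequences", frozenset(self.allowed_consequences)
        )


def is_qualifying(v: VariantRecord, f: QualifyingFilter) -> bool:
    """True iff the consequence is allowed and the rarity cutoff holds."""
    if v.consequence not in f.allowed_consequences:
        return False
    # Exact integer comparison of AC/AN <= max/ref_AN (cross-multiplied),
    # so the AC=10 @ AN=280,000 boundary is inclusive with no float fuzz.
    return (
        v.pop_allele_count * f.reference_allele_number
        <= f.max_pop_allele_count * v.pop_allele_number
    )


def classify_consequence(
    annotation_term: str,
    ref: str = "",
    alt: str = "",
    mapping: Mapping[str, str] | None = None,
) -> str:
    """Map a Sequence-Ontology-style term to a consequence class.

    Compound VEP terms joined by ``&`` are split and the first term with a
    non-``other`` mapping wins.  ``frameshift_variant`` is disambiguated
    into insertion/deletion by comparing REF and ALT lengths; with no
    alleles given it defaults to deletion (the commoner frameshift mode).
    """
    if not annotation_term:
        raise ValueError("empty consequence term")
    table = DEFAULT_CONSEQUENCE_MAP if mapping is None else mapping
    for term in annotation_term.split("&"):
        cls = table.get(term.strip())
        if cls is None:
            continue
        if cls == "frameshift":
            if ref and alt and len(alt) > len(ref):
                return "frameshift_insertion"
            return "frameshift_deletion"
        return cls
    return "other"


def load_consequence_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (term, class) whitespace-separated mapping file.

    Lines starting with ``#`` and blank lines are ignored.  Classes must
    be known; ``frameshift`` is accepted as the length-disambiguated
    placeholder.
    """
    table: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise VcfFormatError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}"
            )
        term, cls = parts
        if cls not in CONSEQUENCE_CLASSES and cls != "frameshift":
            raise VcfFormatError(f"{path}:{lineno}: unknown class {cls!r}")
        table[term] = cls
    return table


_DIALECTS = ("info_tags", "vep_csq", "snpeff_ann")


def read_vcf(
    path: str | Path,
    annotation_dialect: str = "info_tags",
    consequence_map: Mapping[str, str] | None = None,
) -> Iterator[VariantRecord]:
    """Yield one :class:`VariantRecord` per (site, ALT allele).

    Population AC/AN default to 0 / 280,000 when the annotation source
    carries no population counts for an allele: an allele absent from the
    reference population is maximally rare, not missing data.

    Raises
    ------
    VcfFormatError
        for an unknown dialect, a record missing a required annotation
        field, or an uninterpretable genotype.
    """
    if annotation_dialect not in _DIALECTS:
        raise VcfFormatError(
            f"unknown annotation dialect {annotation_dialect!r}; "
            f"expected one of {_DIALECTS}"
        )
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    csq_fields = _csq_fields(vcf, path) if annotation_dialect == "vep_csq" else None
    try:
        for var in vcf:
            alts = var.ALT or []
            gt = var.genotypes  # [[a0, a1, phased], ...]
            for alt_idx, alt in enumerate(alts):
                ann = _annotate(var, alt_idx, alt, annotation_dialect,
                                consequence_map, path, csq_fields)
                if ann is None:
                    continue
                gene, cls, ac, an = ann
                doses = _dosages(gt, samples, alt_idx, var, path)
                yield VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    gene=gene,
                    consequence=cls,
                    pop_allele_count=ac,
                    pop_allele_number=an,
                    genotypes=doses,
                )
    finally:
        vcf.close()


def _dosages(gt, samples, alt_idx, var, path) -> dict[str, int]:
    allele = alt_idx + 1
    out: dict[str, int] = {}
    for sample, call in zip(samples, gt):
        alleles = call[:-1]  # last slot is phasing flag
        if any(a is None for a in alleles):
            raise VcfFormatError(
                f"{path}: malformed genotype for sample {sample} at "
                f"{var.CHROM}:{var.POS}"
            )
        if any(a < 0 for a in alleles):
            out[sample] = MISSING
        else:
            out[sample] = sum(1 for a in alleles if a == allele)
    return out


def _info_scalar(var, key, alt_idx, n_alts):
    val = var.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, tuple):
        return val[alt_idx] if len(val) == n_alts else val[0]
    if isinstance(val, str) and "," in val:
        parts = val.split(",")
        return parts[alt_idx] if len(parts) == n_alts else parts[0]
    return val


def _annotate(var, alt_idx, alt, dialect, cmap, path, csq_fields=None):
    n_alts = len(var.ALT)
    where = f"{path}: record {var.CHROM}:{var.POS} REF={var.REF} ALT={alt}"
    if dialect == "info_tags":
        gene = _info_scalar(var, "GENE", alt_idx, n_alts)
        term = _info_scalar(var, "CSQ_CLASS", alt_idx, n_alts)
        if gene is None or term is None:
            raise VcfFormatError(f"{where}: missing GENE or CSQ_CLASS INFO tag")
        ac = _info_scalar(var, "POP_AC", alt_idx, n_alts)
        an = _info_scalar(var, "POP_AN", alt_idx, n_alts)
        cls = classify_consequence(str(term), var.REF, alt, cmap)
        return str(gene), cls, _to_count(ac, 0), _to_count(an, 280_000)

    if dialect == "vep_csq":
        raw = var.INFO.get("CSQ")
        if raw is None:
            raise VcfFormatError(f"{where}: missing CSQ INFO field")
        fields = csq_fields
        for entry in str(raw).split(","):
            vals = entry.split("|")
            rec = dict(zip(fields, vals))
            if rec.get("Allele") not in (alt, _vep_minimal_allele(var.REF, alt)):
                continue
            term = rec.get("Consequence", "")
            gene = rec.get("SYMBOL") or rec.get("Gene")
            if not gene or not term:
                raise VcfFormatError(f"{where}: CSQ entry lacks SYMBOL/Consequence")
            ac = rec.get("gnomAD_AC") or rec.get("gnomADe_AC")
            an = rec.get("gnomAD_AN") or rec.get("gnomADe_AN")
            cls = classify_consequence(term, var.REF, alt, cmap)
            return gene, cls, _to_count(ac, 0), _to_count(an, 280_000)
        return None  # no CSQ entry for this ALT: unannotated allele

    # snpeff_ann
    raw = var.INFO.get("ANN")
    if raw is None:
        raise VcfFormatError(f"{where}: missing ANN INFO field")
    for entry in str(raw).split(","):
        vals = entry.split("|")
        if len(vals) < 4:
            raise VcfFormatError(f"{where}: ANN entry has fewer than 4 fields")
        if vals[0] != alt:
            continue
        term, gene = vals[1], vals[3]
        if not gene:
            raise VcfFormatError(f"{where}: ANN entry lacks gene name")
        ac = _info_scalar(var, "POP_AC", alt_idx, n_alts)
        an = _info_scalar(var, "POP_AN", alt_idx, n_alts)
        cls = classify_consequence(term, var.REF, alt, cmap)
        return gene, cls, _to_count(ac, 0), _to_count(an, 280_000)
    return None


def _csq_fields(vcf: VCF, path) -> list[str]:
    # header line: Description="Consequence annotations from VEP. Format: A|B|C"
    try:
        desc = vcf.get_header_type("CSQ").get("Description", "")
    except KeyError:
        raise VcfFormatError(f"{path}: no CSQ definition in header") from None
    marker = "Format:"
    if marker not in desc:
        raise VcfFormatError(f"{path}: CSQ header Description lacks 'Format:'")
    fmt = desc.split(marker, 1)[1].strip().strip('"').strip()
    return [f.strip() for f in fmt.split("|")]


def _to_count(val, default: int) -> int:
    if val is None or val == "" or (isinstance(val, float) and math.isnan(val)):
        return default
    return int(float(val))


def _vep_minimal_allele(ref: str, alt: str) -> str:
    """VEP trims the shared leading base for indels ('-' for pure deletion)."""
    if len(ref) > 1 and len(alt) >= 1 and ref[0] == alt[0]:
        return alt[1:] or "-"
    return alt
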