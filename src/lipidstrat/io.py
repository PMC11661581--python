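"""Fixture readers and writers: VCF v4.2 genotypes, phenotype CSV,
ultrasound CSV, reference-score CSV.

The VCF writer emits plain uncompressed text (one sample column per
participant, GT subfield only); reading goes through pysam so user-supplied
VCFs behave identically to generated fixtures.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import classify as cls
from . import ultrasound as us
from .prs import ApoeHaplotype, Band, PrsModel, VariantAnnotation, oriented_dosage
from .simulate import CohortSpec, ReferencePopulation

__all__ = [
    "read_phenotypes",
    "read_reference_scores",
    "read_ultrasound",
    "read_vcf_dosages",
    "write_fixtures",
    "write_phenotypes",
    "write_reference_scores",
    "write_ultrasound",
    "write_vcf",
]

#: GRCh37 coordinates of the two APOE-defining SNPs.
APOE_SNPS = {
    "rs429358": ("19", 45411941, "T", "C"),  # ALT C carries epsilon-4
    "rs7412": ("19", 45412079, "C", "T"),    # ALT T carries epsilon-2
}

_BASES = "ACGT"


def _variant_row(rsid: str, effect_allele: str, index: int):
    """Synthetic placement for score variants: chr1, spaced positions,
    ALT = effect allele, REF = the next base over."""
    if rsid in APOE_SNPS:
        return APOE_SNPS[rsid]
    ref = _BASES[(_BASES.index(effect_allele) + 1) % 4]
    return ("1", 10_000 + 100 * index, ref, effect_allele)


def write_vcf(
    participants: Sequence[cls.Participant],
    ldl_model: PrsModel,
    tg_model: PrsModel,
    path,
) -> Path:
    """VCF v4.2 with GT for every score variant plus rs7412/rs429358."""
    path = Path(path)
    variants = list(ldl_model.variants) + list(tg_model.variants)
    samples = [p.id for p in participants]

    def gt(d: int) -> str:
        return {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]

    hap_counts = {
        ApoeHaplotype.E2E2: (2, 0), ApoeHaplotype.E2E3: (1, 0),
        ApoeHaplotype.E2E4: (1, 1), ApoeHaplotype.E3E3: (0, 0),
        ApoeHaplotype.E3E4: (0, 1), ApoeHaplotype.E4E4: (0, 2),
    }

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lipidstrat-synthetic\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n##contig=<ID=19>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        rows = []
        for i, v in enumerate(variants):
            chrom, pos, ref, alt = _variant_row(v.rsid, v.effect_allele, i)
            gts = []
            for p in participants:
                d = p.__dict__.get("_dosages")
                gts.append(gt(d[i]) if d is not None else "./.")
            rows.append((chrom, pos, v.rsid, ref, alt, gts))
        for rsid in ("rs7412", "rs429358"):
            chrom, pos, ref, alt = APOE_SNPS[rsid]
            gts = []
            for p in participants:
                if p.apoe_haplotype is None:
                    gts.append("./.")
                    continue
                e2, e4 = hap_counts[p.apoe_haplotype]
                gts.append(gt(e2 if rsid == "rs7412" else e4))
            rows.append((chrom, pos, rsid, ref, alt, gts))
        for chrom, pos, rsid, ref, alt, gts in sorted(
            rows, key=lambda r: (r[0], r[1])
        ):
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


def read_vcf_dosages(path, ldl_model: PrsModel, tg_model: PrsModel):
    """Return (dosage DataFrame indexed by sample, apoe genotype dict).

    Dosages are effect-allele counts, flipped when the model effect allele
    sits on the REF side.  The APOE dict maps sample -> (rs7412 alt count,
    rs429358 alt count).
    """
    wanted = {v.rsid: v for v in list(ldl_model.variants) + list(tg_model.variants)}
    order = [v.rsid for v in list(ldl_model.variants) + list(tg_model.variants)]
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    dosage: dict[str, dict[str, float]] = {s: {} for s in samples}
    apoe: dict[str, dict[str, Optional[int]]] = {
        s: {"rs7412": None, "rs429358": None} for s in samples
    }
    for rec in vf:
        rsid = rec.id
        if rsid is None:
            continue
        if len(rec.alts or ()) != 1:
            raise ValueError(f"{rsid}: only biallelic records are supported")
        alt = rec.alts[0]
        for s in samples:
            g = rec.samples[s].get("GT")
            alt_count = (
                None if g is None or any(a is None for a in g) else int(sum(g))
            )
            if rsid in ("rs7412", "rs429358"):
                apoe[s][rsid] = alt_count
            if rsid in wanted:
                if alt_count is None:
                    dosage[s][rsid] = np.nan
                else:
                    dosage[s][rsid] = oriented_dosage(
                        alt_count, rec.ref, alt, wanted[rsid].effect_allele
                    )
    vf.close()
    df = pd.DataFrame.from_dict(dosage, orient="index")
    missing_cols = [r for r in order if r not in df.columns]
    if missing_cols:
        raise ValueError(f"VCF lacks model variants: {missing_cols[:5]} ...")
    df = df[order]
    apoe_pairs = {s: (apoe[s]["rs7412"], apoe[s]["rs429358"]) for s in samples}
    return df, apoe_pairs


# ---------------------------------------------------------------------------
# phenotype CSV

PHENOTYPE_COLUMNS = [
    "participant_id", "sex", "age", "bmi", "smoking", "hypertension",
    "diabetes", "tendon_xanthomas", "tc", "ldl_c", "hdl_c", "tg",
    "ldl_direct", "lpa", "statin_drug", "statin_dose",
    "statin_months_before_ultrasound", "statin_months_historical",
    "chd", "chd_onset_age", "causal_variants", "panel", "intended_group",
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def write_phenotypes(participants: Sequence[cls.Participant], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PHENOTYPE_COLUMNS)
        for p in participants:
            variants = ";".join(
                f"{v.gene}:{v.rsid}:{v.pathogenicity or ''}" for v in p.causal_variants
            )
            s = p.statin
            w.writerow([
                p.id, p.sex, _fmt(p.age), _fmt(p.bmi), p.smoking,
                _fmt(p.hypertension), _fmt(p.diabetes), _fmt(p.tendon_xanthomas),
                _fmt(p.lipids.tc), _fmt(p.lipids.ldl_c), _fmt(p.lipids.hdl_c),
                _fmt(p.lipids.tg), _fmt(p.lipids.ldl_direct), _fmt(p.lipids.lpa),
                s.drug if s else "", _fmt(s.dose if s else None),
                _fmt(s.months_before_ultrasound if s else None),
                _fmt(s.months_historical if s else None),
                _fmt(p.chd), _fmt(p.chd_onset_age), variants, p.panel,
                p.intended_group or "",
            ])
    return path


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def read_phenotypes(path) -> list[cls.Participant]:
    participants = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PHENOTYPE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"phenotype CSV lacks columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                statin = None
                if row["statin_drug"]:
                    statin = cls.StatinTherapy(
                        drug=row["statin_drug"],
                        dose=float(row["statin_dose"]),
                        months_before_ultrasound=float(
                            row["statin_months_before_ultrasound"] or 0
                        ),
                        months_historical=float(row["statin_months_historical"] or 0),
                    )
                causal = []
                if row["causal_variants"]:
                    for item in row["causal_variants"].split(";"):
                        gene, rsid, patho = item.split(":")
                        causal.append(VariantAnnotation(
                            rsid=rsid, gene=gene, pathogenicity=patho or None,
                        ))
                participants.append(cls.Participant(
                    id=row["participant_id"],
                    sex=row["sex"],
                    age=float(row["age"]),
                    lipids=cls.LipidPanel(
                        tc=_opt_float(row["tc"]),
                        ldl_c=_opt_float(row["ldl_c"]),
                        hdl_c=_opt_float(row["hdl_c"]),
                        tg=_opt_float(row["tg"]),
                        ldl_direct=row["ldl_direct"] == "1",
                        lpa=_opt_float(row["lpa"]),
                    ),
                    bmi=_opt_float(row["bmi"]),
                    smoking=row["smoking"],
                    hypertension=row["hypertension"] == "1",
                    diabetes=row["diabetes"] == "1",
                    tendon_xanthomas=row["tendon_xanthomas"] == "1",
                    statin=statin,
                    causal_variants=causal,
                    chd=row["chd"] == "1",
                    chd_onset_age=_opt_float(row["chd_onset_age"]),
                    panel=row["panel"] or "GENES_24",
                    intended_group=row["intended_group"] or None,
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"phenotype CSV row {i}: {exc}") from exc
    return participants


# ---------------------------------------------------------------------------
# ultrasound CSV (one row per plaque; empty-plaque rows keep the site)

ULTRASOUND_COLUMNS = [
    "participant_id", "territory", "side", "site", "segment",
    "surrounding_imt", "height", "encroachment",
    "residual_lumen_area", "original_lumen_area",
]


def write_ultrasound(records: Sequence[us.UltrasoundSiteRecord], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ULTRASOUND_COLUMNS)
        for rec in records:
            base = [rec.participant_id, rec.territory.value, rec.side.value,
                    rec.site.value, rec.segment.value, _fmt(rec.surrounding_imt)]
            if not rec.plaques:
                w.writerow(base + ["", "", "", ""])
            for m in rec.plaques:
                w.writerow(base + [
                    _fmt(m.height), _fmt(m.encroachment),
                    _fmt(m.residual_lumen_area), _fmt(m.original_lumen_area),
                ])
    return path


def read_ultrasound(path) -> list[us.UltrasoundSiteRecord]:
    by_key: dict[tuple, us.UltrasoundSiteRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(ULTRASOUND_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"ultrasound CSV lacks columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["participant_id"], row["territory"], row["side"],
                       row["site"], row["segment"])
                if key not in by_key:
                    by_key[key] = us.UltrasoundSiteRecord(
                        participant_id=row["participant_id"],
                        territory=us.Territory(row["territory"]),
                        side=us.Side(row["side"]),
                        site=us.Site(row["site"]),
                        segment=us.Segment(row["segment"]),
                        surrounding_imt=float(row["surrounding_imt"]),
                    )
                if row["height"]:
                    by_key[key].plaques.append(us.PlaqueMeasurement(
                        height=float(row["height"]),
                        encroachment=float(row["encroachment"]),
                        residual_lumen_area=_opt_float(row["residual_lumen_area"]),
                        original_lumen_area=_opt_float(row["original_lumen_area"]),
                    ))
            except ValueError as exc:
                raise ValueError(f"ultrasound CSV row {i}: {exc}") from exc
    return list(by_key.values())


# ---------------------------------------------------------------------------
# reference scores


def write_reference_scores(reference: ReferencePopulation, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_index", "ldl_score", "tg_score", "apoe_haplotype"])
        for i, (ls, ts, h) in enumerate(
            zip(reference.ldl_scores, reference.tg_scores, reference.haplotypes)
        ):
            w.writerow([i, f"{ls:.10g}", f"{ts:.10g}", h.value])
    return path


def read_reference_scores(path):
    """Return (ldl_scores, tg_scores) arrays from a reference-score CSV."""
    df = pd.read_csv(path)
    return df["ldl_score"].to_numpy(float), df["tg_score"].to_numpy(float)


def write_fixtures(
    population: ReferencePopulation,
    cohort: Sequence[cls.Participant],
    records: Sequence[us.UltrasoundSiteRecord],
    out_dir,
) -> dict[str, Path]:
    """Write the full text fixture set; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "vcf": write_vcf(cohort, population.ldl_model, population.tg_model,
                         out / "cohort.vcf"),
        "phenotypes": write_phenotypes(cohort, out / "phenotypes.csv"),
        "ultrasound": write_ultrasound(records, out / "ultrasound.csv"),
        "reference_scores": write_reference_scores(
            population, out / "reference_scores.csv"
        ),
    }
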