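"""Containers, file formats, pedigree kinship, and the end-to-end pipeline.

Canonical on-disk formats (all plain text):

* genotype TSV — rows = samples, columns = SNPs, values 0/1/2 or NA,
  first column ``sample_id``; provenance comment lines start with ``#``.
* PED/MAP — PLINK-style two-allele-per-SNP dialect; ``0 0`` is missing.
  Dosages count the minor allele (ties broken alphabetically).
* FAM — family, individual, father, mother, sex, affection (0 = missing
  parent).
* phenotype CSV — one row per carrier with the CarrierRecord columns.
* incidence CSV — ``age,hazard`` (see :mod:`carriermod.incidence`).

Sample IDs are case-sensitive strings; missing numeric fields are NA.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("carriermod")

PHENOTYPE_COLUMNS = [
    "sample_id",
    "family_id",
    "stratum",
    "censor_age",
    "breast_event",
    "ovarian_event",
    "mastectomy_age",
    "diagnosis_age",
    "recruitment_age",
    "er_status",
    "mutation_class",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP and per-sample metadata.

    ``dosages``: DataFrame indexed by sample_id, columns = SNP ids, float
    values 0/1/2 with NaN for missing calls.  ``snps``: per-SNP metadata
    (alleles, target MAF where known).  ``samples``: per-sample metadata
    (family, parents, sex, stratum) when the matrix came from a simulated
    or pedigree-annotated source.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    true_dosages: pd.DataFrame | None = None  # pre-missingness, simulation only

    @property
    def sample_ids(self) -> np.ndarray:
        return self.dosages.index.to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.dosages.columns.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


class KinshipModel:
    """Pairwise kinship coefficients φ from a pedigree, by family.

    φ_ii = 1/2 for non-inbred individuals; dosage correlation between two
    members is 2φ.  Only within-family pairs are stored (between families
    φ = 0).  ``pairs_for`` returns the non-zero off-diagonal pairs among a
    requested sample subset as index triples (i, j, 2φ_ij), each unordered
    pair once — the form needed for the score-variance quadratic form.
    """

    def __init__(self, phi: dict[tuple[str, str], float], family_of: dict[str, str]):
        self._phi = phi
        self._family_of = family_of
        self._members: dict[str, list[str]] = {}
        for sid, fam in family_of.items():
            self._members.setdefault(fam, []).append(sid)
        self._pair_cache: dict[int, tuple] = {}

    def phi(self, a: str, b: str) -> float:
        if a == b:
            return self._phi.get((a, a), 0.5)
        if self._family_of.get(a) != self._family_of.get(b):
            return 0.0
        return self._phi.get((min(a, b), max(a, b)), 0.0)

    def family_of(self, sample_id: str) -> str | None:
        return self._family_of.get(sample_id)

    def pairs_for(self, sample_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids = list(sample_ids)
        key = hash(tuple(ids))
        if key in self._pair_cache:
            return self._pair_cache[key]
        pos = {s: i for i, s in enumerate(ids)}
        by_fam: dict[str, list[str]] = {}
        for s in ids:
            fam = self._family_of.get(s)
            if fam is not None:
                by_fam.setdefault(fam, []).append(s)
        ii, jj, w = [], [], []
        for members in by_fam.values():
            for a_idx in range(len(members)):
                for b_idx in range(a_idx + 1, len(members)):
                    a, b = members[a_idx], members[b_idx]
                    ph = self._phi.get((min(a, b), max(a, b)), 0.0)
                    if ph != 0.0:
                        ii.append(pos[a])
                        jj.append(pos[b])
                        w.append(2.0 * ph)
        out = (
            np.asarray(ii, dtype=int),
            np.asarray(jj, dtype=int),
            np.asarray(w, dtype=float),
        )
        if len(self._pair_cache) < 64:
            self._pair_cache[key] = out
        return out


def compute_kinship(pedigree: pd.DataFrame) -> KinshipModel:
    """Recursive kinship coefficients over a FAM-style pedigree.

    Standard recursion: founders are unrelated and non-inbred; for a
    non-founder i with parents (f, m) and any j processed before i,
    φ(i, j) = (φ(f, j) + φ(m, j))/2 and φ(i, i) = 1/2 + φ(f, m)/2.
    Parent IDs of "0" (or empty/NaN) mean founder.  A pedigree cycle
    raises ``ValueError``.
    """
    ped = pedigree.copy()
    ped["individual_id"] = ped["individual_id"].astype(str)
    phi: dict[tuple[str, str], float] = {}
    family_of: dict[str, str] = {}

    def norm(v):
        s = "" if pd.isna(v) else str(v)
        return None if s in ("", "0", "nan") else s

    for fam, group in ped.groupby("family_id", sort=True):
        members = group["individual_id"].tolist()
        parents = {
            r.individual_id: (norm(r.father_id), norm(r.mother_id))
            for r in group.itertuples()
        }
        # topological order: parents before children
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(x: str, stack: tuple = ()):  # noqa: B006
            if x not in parents:
                return  # parent outside the table: treat as founder
            if state.get(x) == 2:
                return
            if state.get(x) == 1:
                raise ValueError(f"pedigree cycle detected in family {fam!r} at {x!r}")
            state[x] = 1
            for p in parents[x]:
                if p is not None:
                    visit(p)
            state[x] = 2
            order.append(x)

        for m in members:
            visit(m)

        def get(a: str, b: str) -> float:
            if a == b:
                return phi.get((a, a), 0.5)
            return phi.get((min(a, b), max(a, b)), 0.0)

        for idx, x in enumerate(order):
            f, m = parents[x]
            f = f if f in parents else None
            m = m if m in parents else None
            if f is None and m is None:
                phi[(x, x)] = 0.5
            else:
                pf = get(f, m) if (f and m) else 0.0
                phi[(x, x)] = 0.5 + 0.5 * pf
            for y in order[:idx]:
                if f is None and m is None:
                    val = 0.0
                else:
                    val = 0.5 * ((get(f, y) if f else 0.0) + (get(m, y) if m else 0.0))
                if val != 0.0:
                    phi[(min(x, y), max(x, y))] = val
            family_of[x] = str(fam)
    return KinshipModel(phi, family_of)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_genotypes(gm: GenotypeMatrix, path, header_meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df = gm.dosages.copy()
        df.index.name = "sample_id"
        out = df.reset_index()
        out.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_genotypes(path, dialect: str = "tsv", map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or PED(+MAP)."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        dos = df.astype(float)
        bad = [
            c
            for c in dos.columns
            if not dos[c].dropna().isin([0.0, 1.0, 2.0]).all()
        ]
        if bad:
            raise ValueError(f"non-biallelic dosage values in SNP(s) {bad[:5]}")
        return GenotypeMatrix(dos)
    if dialect == "ped_map":
        return _read_ped_map(path, map_path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    if map_path is None:
        map_path = str(ped_path).rsplit(".", 1)[0] + ".map"
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype=str,
    )
    snp_ids = mp["snp"].tolist()
    rows = []
    meta = []
    with open(ped_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            fam, iid, fid, mid, sex, pheno = parts[:6]
            alleles = parts[6:]
            if len(alleles) != 2 * len(snp_ids):
                raise ValueError(
                    f"PED row for {iid} has {len(alleles)} allele fields, "
                    f"expected {2 * len(snp_ids)}"
                )
            meta.append((fam, iid, fid, mid, sex, pheno))
            rows.append(alleles)
    allele_arr = np.asarray(rows, dtype=object).reshape(len(rows), len(snp_ids), 2)
    dosages = np.full((len(rows), len(snp_ids)), np.nan)
    a_alleles, b_alleles = [], []
    for k in range(len(snp_ids)):
        pair = allele_arr[:, k, :]
        called = pair[(pair != "0").all(axis=1)]
        uniq, counts = np.unique(called, return_counts=True)
        uniq = [u for u in uniq]
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_ids[k]} is not biallelic: alleles {uniq}")
        if len(uniq) == 0:
            a, b = "0", "0"
        elif len(uniq) == 1:
            a, b = uniq[0], uniq[0]
        else:
            order = np.argsort(counts, kind="stable")
            # minor allele = less frequent; alphabetical on ties
            if counts[0] == counts[1]:
                a, b = sorted(uniq)
            else:
                a, b = uniq[order[0]], uniq[order[1]]
        a_alleles.append(a)
        b_alleles.append(b)
        miss = (pair == "0").any(axis=1)
        dosages[:, k] = np.where(miss, np.nan, (pair == a).sum(axis=1))
    meta_df = pd.DataFrame(
        meta,
        columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "affection"],
    )
    dos = pd.DataFrame(
        dosages, index=meta_df["sample_id"].astype(str), columns=snp_ids
    )
    snps = pd.DataFrame({"snp": snp_ids, "minor_allele": a_alleles, "major_allele": b_alleles})
    return GenotypeMatrix(dos, snps=snps, samples=meta_df)


def write_fam(pedigree: pd.DataFrame, path) -> None:
    cols = ["family_id", "individual_id", "father_id", "mother_id", "sex", "affection"]
    pedigree[cols].to_csv(path, sep="\t", index=False, header=False)


def read_fam(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "affection"],
        dtype={"family_id": str, "individual_id": str, "father_id": str, "mother_id": str},
    )


def write_phenotypes(records: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        records.to_csv(fh, index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", na_values=["NA"])
    df["sample_id"] = df["sample_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips through YAML unchanged."""

    genotypes: str | None = None
    phenotypes: str | None = None
    pedigree: str | None = None
    incidence: str | None = None
    ovarian_incidence: str | None = None
    loci: str | None = None  # risk-profile panel TSV (snp, maf, hr)
    strata_column: str = "stratum"
    out_dir: str = "carriermod_out"
    seed: int = 1
    simulate: dict | None = None  # SyntheticConfig overrides; None = use files
    call_rate_threshold: float = 0.95
    hwe_p_threshold: float = 1e-7
    het_p_threshold: float = 1e-6
    duplicate_discordance_threshold: float = 0.05
    competing_risks: bool = False
    subtype_er: bool = False
    interaction_tests: bool = True
    profile_ages: tuple = (50, 80)
    profile_percentiles: tuple = (5, 95)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("profile_ages", "profile_percentiles"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (optional) -> QC -> association -> inflation -> risk profile.

    Returns a dict of result objects; writes TSV outputs (with seed and
    config-hash provenance headers) and a plain-text log of per-stage
    counts under ``config.out_dir``.  Any stage failure aborts with the
    stage name in the exception.
    """
    from . import qc as qc_mod
    from . import gcontrol, profile_risk, synthetic
    from .incidence import IncidenceCurve, default_breast_incidence
    from . import retrospective as retro

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    t0 = time.time()
    results: dict = {}
    try:
        stage = "input"
        if config.simulate is not None:
            scfg = synthetic.SyntheticConfig(seed=config.seed, **config.simulate)
            gm, pedigree = synthetic.simulate_families(scfg)
            records = synthetic.simulate_phenotypes(gm, scfg)
            records = synthetic.apply_ascertainment(
                records, scfg.ascertainment_policy, seed=scfg.seed + 1
            )
            incidence = scfg.incidence
            write_genotypes(gm, out / "genotypes.tsv", meta)
            write_fam(pedigree, out / "pedigree.fam")
            write_phenotypes(records, out / "phenotypes.csv", meta)
        else:
            gm = read_genotypes(config.genotypes)
            records = read_phenotypes(config.phenotypes)
            pedigree = read_fam(config.pedigree) if config.pedigree else None
            incidence = (
                IncidenceCurve.read_csv(config.incidence)
                if config.incidence
                else default_breast_incidence()
            )
        log.info("input: %d samples, %d SNPs, %d phenotype records",
                 gm.n_samples, gm.n_snps, len(records))

        stage = "qc"
        strata_of = records.set_index("sample_id")[config.strata_column]
        strata = strata_of.reindex(gm.dosages.index).fillna("unknown").to_numpy()
        snp_report = qc_mod.snp_qc(
            gm,
            strata,
            call_rate=config.call_rate_threshold,
            hwe_p=config.hwe_p_threshold,
        )
        sample_report = qc_mod.sample_qc(
            gm,
            duplicates=None,
            call_rate=config.call_rate_threshold,
            het_p=config.het_p_threshold,
            discordance=config.duplicate_discordance_threshold,
        )
        keep_snps = snp_report.loc[~snp_report["excluded"], "snp"]
        keep_samples = sample_report.loc[~sample_report["excluded"], "sample_id"]
        snp_report.to_csv(out / "snp_qc.tsv", sep="\t", index=False)
        sample_report.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        log.info("qc: retained %d/%d SNPs, %d/%d samples",
                 len(keep_snps), gm.n_snps, len(keep_samples), gm.n_samples)
        dosages = gm.dosages.loc[gm.dosages.index.isin(set(keep_samples)), list(keep_snps)]
        records = records[records["sample_id"].isin(set(dosages.index))].reset_index(drop=True)
        dosages = dosages.reindex(records["sample_id"])

        stage = "association"
        kinship = compute_kinship(pedigree) if pedigree is not None else None
        rows = []
        for snp in dosages.columns:
            res = retro.fit_per_allele(
                records,
                dosages[snp].to_numpy(float),
                incidence,
                strata=config.strata_column,
                kinship=kinship,
                snp=str(snp),
            )
            row = {
                "snp": res.snp,
                "n_aff": res.n_affected,
                "n_unaff": res.n_unaffected,
                "maf_unaff": res.maf_unaffected,
                "beta": res.beta,
                "se": res.se,
                "hr": res.hr,
                "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi,
                "score_chi2": res.score_chi2,
                "p": res.p,
            }
            if config.interaction_tests:
                het = retro.country_heterogeneity_test(
                    records, dosages[snp].to_numpy(float), incidence,
                    strata=config.strata_column,
                )
                inter = retro.genotype_age_interaction_test(
                    records, dosages[snp].to_numpy(float), incidence,
                    strata=config.strata_column,
                )
                row["het_country_p"] = het[2]
                row["age_interaction_p"] = inter[1]
            rows.append(row)
        assoc = pd.DataFrame(rows)
        with open(out / "results.tsv", "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            assoc.to_csv(fh, sep="\t", index=False, na_rep="NA")
        results["association"] = assoc
        log.info("association: %d SNPs tested", len(assoc))

        stage = "genomic_control"
        if len(assoc) and assoc["score_chi2"].notna().any():
            gc_rep = gcontrol.gc_report(
                assoc["score_chi2"].dropna().to_numpy(),
                n_affected=int(records["breast_event"].sum()),
                n_unaffected=int((1 - records["breast_event"]).sum()),
            )
            gc_rep.qq.to_csv(out / "qq.tsv", sep="\t", index=False)
            (out / "gc.tsv").write_text(
                "lambda\tlambda_1000\tn_affected\tn_unaffected\n"
                f"{gc_rep.lam:.6f}\t{gc_rep.lam_1000:.6f}\t"
                f"{gc_rep.n_affected}\t{gc_rep.n_unaffected}\n"
            )
            results["gc"] = gc_rep
            log.info("genomic_control: lambda=%.4f lambda_1000=%.4f",
                     gc_rep.lam, gc_rep.lam_1000)
        else:
            log.info("genomic_control: skipped (no tested SNPs)")

        stage = "risk_profile"
        if config.loci:
            loci = profile_risk.read_loci(config.loci)
            summary = profile_risk.absolute_risk_percentiles(
                loci,
                incidence,
                ages=config.profile_ages,
                percentiles=config.profile_percentiles,
            )
            summary.to_csv(out / "profile_risk.tsv", sep="\t", index=False)
            results["profile"] = summary
            log.info("risk_profile: %d loci", len(loci))
        results["snp_qc"] = snp_report
        results["sample_qc"] = sample_report
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return results
    except Exception as exc:  # annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
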