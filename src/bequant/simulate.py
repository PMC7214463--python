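"""Synthetic-data generators with known ground truth.

Every input the analysis consumes can be generated here: amplicons with
planted protospacers, mosaic embryo clone sets, lineage-structured
blastomere clone sets, joint-genotyped trio variant tables with planted
de novo variants and single-defect artifacts, and genomes with planted
mismatch off-target sites. All generators are fully deterministic under
``SimConfig.seed``; independent random streams are used per component so
changing one rate does not perturb unrelated draws.

The editing model emulated: each zygotic allele is independently edited
(per-position Bernoulli conversion inside the activity window, a lower
bystander rate outside it, plus unintended-substitution and indel
events); clones are sampled from the allele pool with multiplicity
noise, and uniform sequencing errors exercise the background-mismatch
tolerance. Mosaicism arises from a two-branch lineage (zygote -> 2
cells) on which editing events may differ.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .editors import EditorSpec, IUPAC, TargetSite, build_editor_spec, locate_protospacer, revcomp
from .denovo import ROLES, SampleCall, TrioVariantRecord
from .offtarget import OfftargetSite

ARTIFACT_CLASSES = (
    "low_qual", "low_gq", "low_dp", "parent_leak", "allele_balance", "density_cluster",
)

# per-component random streams
_STREAM_SEQUENCE = 0
_STREAM_EVENTS = 1
_STREAM_SAMPLING = 2
_STREAM_TRIO = 3
_STREAM_GENOME = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Embryo-editing defaults mirror the observed single-site outcome mix
    (majority of injected embryos edited, mosaic allele pools, occasional
    non-product conversions and indels); trio defaults give a
    thousand-variant table with a germline-scale planted de novo load and
    artifact classes that each violate exactly one downstream filter.
    """

    seed: int
    # amplicon / editing
    intended_rate: float = 0.6
    bystander_rate: float = 0.1
    unintended_rate: float = 0.05
    indel_rate: float = 0.1
    seq_error_rate: float = 1e-3
    clones_per_embryo: int = 10
    allele_pool: str = "zygote"  # "zygote" (2 alleles) or "per-clone"
    amplicon_len: int = 160
    n_editable: int = 2
    # blastomeres
    n_blastomeres: int = 5
    clones_per_blastomere: int = 8
    coediting_correlation: float = 0.8
    # trio
    n_variants: int = 1000
    n_true_denovo: int = 20
    denovo_indel_fraction: float = 0.1
    artifact_counts: tuple[tuple[str, int], ...] = (
        ("low_qual", 8), ("low_gq", 8), ("low_dp", 8),
        ("parent_leak", 8), ("allele_balance", 8), ("density_cluster", 10),
    )
    # genome / off-targets
    genome_len: int = 50_000
    planted_mismatches: tuple[int, ...] = (1, 1, 2, 2, 3, 3, 4)

    def __post_init__(self) -> None:
        for name in ("intended_rate", "bystander_rate", "unintended_rate",
                     "indel_rate", "seq_error_rate", "coediting_correlation",
                     "denovo_indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("clones_per_embryo", "n_blastomeres", "clones_per_blastomere",
                     "amplicon_len", "n_variants", "genome_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.allele_pool not in ("zygote", "per-clone"):
            raise ValueError("allele_pool must be 'zygote' or 'per-clone'")
        counts = dict(self.artifact_counts)
        unknown = set(counts) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")
        if counts.get("density_cluster", 0) % 5 != 0:
            raise ValueError("density_cluster count must be a multiple of 5")
        n_art = sum(counts.values())
        if self.n_true_denovo + n_art > self.n_variants:
            raise ValueError("n_variants too small for de novos + artifacts")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "artifact_counts" in data and isinstance(data["artifact_counts"], dict):
            data["artifact_counts"] = tuple(sorted(data["artifact_counts"].items()))
        if "planted_mismatches" in data:
            data["planted_mismatches"] = tuple(data["planted_mismatches"])
        return cls(**data)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _realize_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def gen_site(
    config: SimConfig,
    editor: EditorSpec | str = "BE3",
    locus: str = "SIM",
) -> tuple[str, TargetSite]:
    """Random amplicon with one planted protospacer+PAM on the plus strand.

    ``config.n_editable`` substrate bases are forced into the activity
    window (error if the window cannot hold them); the spacer+PAM occur
    exactly once in the amplicon (resampled otherwise).
    """
    if isinstance(editor, str):
        editor = build_editor_spec(editor)
    window_size = editor.window[1] - editor.window[0] + 1
    if config.n_editable > window_size:
        raise ValueError(
            f"requested {config.n_editable} editable positions but the "
            f"window holds only {window_size}"
        )
    rng = _rng(config, _STREAM_SEQUENCE)
    span = editor.spacer_len + len(editor.pam)
    if config.amplicon_len < span + 20:
        raise ValueError("amplicon_len too small for spacer + PAM + flanks")
    for _ in range(100):
        spacer = list(_random_seq(rng, editor.spacer_len))
        # clear stray substrate bases in the window, then plant exactly n_editable
        window_positions = list(range(editor.window[0], editor.window[1] + 1))
        others = [b for b in "ACGT" if b != editor.substrate]
        for p in window_positions:
            if spacer[p - 1] == editor.substrate:
                spacer[p - 1] = rng.choice(others)
        chosen = rng.choice(window_positions, size=config.n_editable, replace=False)
        for p in chosen:
            spacer[p - 1] = editor.substrate
        spacer_str = "".join(spacer)
        pam = _realize_pam(rng, editor.pam)
        amplicon = list(_random_seq(rng, config.amplicon_len))
        offset = int(rng.integers(10, config.amplicon_len - span - 10))
        amplicon[offset:offset + span] = list(spacer_str + pam)
        amplicon_str = "".join(amplicon)
        try:
            site = locate_protospacer(amplicon_str, spacer_str, editor, locus=locus)
        except ValueError:
            continue
        return amplicon_str, site
    raise RuntimeError("failed to generate a unique protospacer placement")


@dataclass(frozen=True)
class AlleleEvents:
    """Generative description of one edited allele."""

    intended: tuple[int, ...]            # protospacer positions converted
    unintended: tuple[tuple[int, str], ...]  # (position, observed base)
    deletion: tuple[int, int] | None      # (protospacer start position, length)

    @property
    def is_wt(self) -> bool:
        return not self.intended and not self.unintended and self.deletion is None


def build_allele_sequence(site: TargetSite, editor: EditorSpec, events: AlleleEvents) -> str:
    """Apply generative events to the reference amplicon (plus strand)."""
    seq = list(site.amplicon_ref)
    for p in events.intended:
        base = editor.product
        seq[site.plus_index(p)] = base if site.strand == "+" else revcomp(base)
    for p, base in events.unintended:
        seq[site.plus_index(p)] = base if site.strand == "+" else revcomp(base)
    if events.deletion is not None:
        start_p, length = events.deletion
        lo = site.plus_index(start_p)
        if site.strand == "-":
            lo = lo - length + 1
        lo = max(0, lo)
        del seq[lo:lo + length]
    return "".join(seq)


def _draw_allele(site: TargetSite, editor: EditorSpec, config: SimConfig,
                 rng: np.random.Generator) -> AlleleEvents:
    intended = []
    for p, base, in_window in site.substrate_positions:
        rate = config.intended_rate if in_window else config.bystander_rate
        if rng.random() < rate:
            intended.append(p)
    unintended = []
    if rng.random() < config.unintended_rate:
        p = int(rng.integers(1, site.spacer_len + 1))
        ref_base = site.spacer[p - 1]
        forbidden = {ref_base}
        if ref_base == editor.substrate:
            forbidden.add(editor.product)
        base = rng.choice([b for b in "ACGT" if b not in forbidden])
        unintended.append((p, str(base)))
        intended = [q for q in intended if q != p]
    deletion = None
    if rng.random() < config.indel_rate:
        length = int(rng.integers(1, 7))
        start_p = int(rng.integers(editor.window[0], editor.window[1] + 1))
        deletion = (start_p, length)
    return AlleleEvents(tuple(sorted(intended)), tuple(unintended), deletion)


def sim_embryo_clones(
    site: TargetSite,
    editor: EditorSpec,
    config: SimConfig,
    embryo_id: str = "E1",
    blastomere_id: str = "-",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Clones sampled from a mosaic zygotic allele pool, with truth table.

    ``allele_pool="zygote"`` edits 2 alleles and samples clones from them
    (multiplicity noise); ``"per-clone"`` draws an independent allele per
    clone, which makes per-position clone counts exactly binomial.
    Returns ``[(clone_id, sequence)]`` and a truth DataFrame recording
    each clone's generative allele.
    """
    ev_rng = _rng(config, _STREAM_EVENTS)
    samp_rng = _rng(config, _STREAM_SAMPLING)
    n = config.clones_per_embryo
    if config.allele_pool == "zygote":
        pool = [_draw_allele(site, editor, config, ev_rng) for _ in range(2)]
        assignment = samp_rng.integers(0, 2, size=n)
    else:
        pool = [_draw_allele(site, editor, config, ev_rng) for _ in range(n)]
        assignment = np.arange(n)
    clones: list[tuple[str, str]] = []
    rows = []
    for i in range(n):
        allele = pool[int(assignment[i])]
        seq = build_allele_sequence(site, editor, allele)
        n_err = samp_rng.binomial(len(seq), config.seq_error_rate)
        if n_err:
            seq_list = list(seq)
            for j in samp_rng.choice(len(seq_list), size=n_err, replace=False):
                seq_list[j] = samp_rng.choice(
                    [b for b in "ACGT" if b != seq_list[j]]
                )
            seq = "".join(seq_list)
        clone_id = f"{embryo_id}|{blastomere_id}|c{i + 1}"
        clones.append((clone_id, seq))
        rows.append({
            "clone_id": clone_id,
            "embryo_id": embryo_id,
            "blastomere_id": blastomere_id,
            "allele_index": int(assignment[i]),
            "intended_positions": ",".join(map(str, allele.intended)),
            "unintended_positions": ",".join(f"{p}:{b}" for p, b in allele.unintended),
            "has_indel": allele.deletion is not None,
            "n_seq_errors": int(n_err),
        })
    return clones, pd.DataFrame(rows)


def _truth_site_call(pair: tuple[AlleleEvents, AlleleEvents]) -> str:
    """Genotype implied by an allele pair, mirroring the blastomere caller."""
    if any(a.deletion is not None for a in pair):
        return "indel"
    if any(a.unintended for a in pair):
        return "unintended"
    intended = [bool(a.intended) for a in pair]
    if all(intended):
        return "hom_edited"
    if any(intended):
        return "het_edited"
    return "WT"


def sim_blastomeres(
    sites_editors: list[tuple[TargetSite, EditorSpec]],
    config: SimConfig,
    embryo_id: str = "E1",
) -> tuple[dict[str, dict[str, list[tuple[str, str]]]], pd.DataFrame]:
    """Lineage-structured blastomere clone sets with truth genotypes.

    Editing events land on a two-branch lineage (zygote -> 2 cells);
    blastomeres alternate between branches, so sister blastomeres can
    share or differ in genotype. ``coediting_correlation`` couples
    editing across sites within an allele: with probability ``c`` a
    site reuses the allele's shared latent draw, so sites are co-edited.
    Returns clones keyed ``blastomere -> site locus`` plus a truth frame.
    """
    if config.n_blastomeres < 2:
        raise ValueError("at least 2 blastomeres required")
    ev_rng = _rng(config, _STREAM_EVENTS)
    # branch -> allele index -> site locus -> AlleleEvents
    branches: list[list[dict[str, AlleleEvents]]] = []
    for _branch in range(2):
        alleles = []
        for _a in range(2):
            shared_u = ev_rng.random()
            per_site: dict[str, AlleleEvents] = {}
            for site, editor in sites_editors:
                use_shared = ev_rng.random() < config.coediting_correlation
                intended = []
                for p, base, in_window in site.substrate_positions:
                    rate = config.intended_rate if in_window else config.bystander_rate
                    u = shared_u if (use_shared and in_window) else ev_rng.random()
                    if u < rate:
                        intended.append(p)
                unintended = []
                if ev_rng.random() < config.unintended_rate:
                    p = int(ev_rng.integers(1, site.spacer_len + 1))
                    ref_base = site.spacer[p - 1]
                    forbidden = {ref_base}
                    if ref_base == editor.substrate:
                        forbidden.add(editor.product)
                    base = str(ev_rng.choice([b for b in "ACGT" if b not in forbidden]))
                    unintended.append((p, base))
                    intended = [q for q in intended if q != p]
                deletion = None
                if ev_rng.random() < config.indel_rate:
                    deletion = (
                        int(ev_rng.integers(editor.window[0], editor.window[1] + 1)),
                        int(ev_rng.integers(1, 7)),
                    )
                per_site[site.locus] = AlleleEvents(
                    tuple(sorted(intended)), tuple(unintended), deletion
                )
            alleles.append(per_site)
        branches.append(alleles)

    samp_rng = _rng(config, _STREAM_SAMPLING)
    clones_out: dict[str, dict[str, list[tuple[str, str]]]] = {}
    rows = []
    for b in range(config.n_blastomeres):
        bid = f"B{b + 1}"
        branch = branches[b % 2]
        clones_out[bid] = {}
        for site, editor in sites_editors:
            pair = (branch[0][site.locus], branch[1][site.locus])
            site_clones = []
            for i in range(config.clones_per_blastomere):
                allele = pair[int(samp_rng.integers(0, 2))]
                seq = build_allele_sequence(site, editor, allele)
                n_err = samp_rng.binomial(len(seq), config.seq_error_rate)
                if n_err:
                    seq_list = list(seq)
                    for j in samp_rng.choice(len(seq_list), size=n_err, replace=False):
                        seq_list[j] = samp_rng.choice(
                            [x for x in "ACGT" if x != seq_list[j]]
                        )
                    seq = "".join(seq_list)
                site_clones.append((f"{embryo_id}|{bid}|c{i + 1}", seq))
            clones_out[bid][site.locus] = site_clones
            rows.append({
                "embryo_id": embryo_id,
                "blastomere_id": bid,
                "site": site.locus,
                "branch": b % 2,
                "truth_call": _truth_site_call(pair),
            })
    return clones_out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trio variant tables


_TRIO_CONTIGS = {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000, "chr4": 50_000_000}


@dataclass(frozen=True)
class TrioSim:
    records: list[TrioVariantRecord]
    pileups: dict[tuple[str, int], dict[str, tuple[int, int]]]
    truth: pd.DataFrame
    contigs: dict[str, int]


def _clean_annotations(rng: np.random.Generator) -> tuple[dict[str, float], float]:
    annotations = {
        "QD": round(float(rng.uniform(15, 30)), 2),
        "FS": round(float(rng.uniform(0, 3)), 3),
        "MQ": 60.0,
        "MQRankSum": round(float(rng.normal(0, 0.3)), 3),
        "ReadPosRankSum": round(float(rng.normal(0, 0.3)), 3),
    }
    qual = round(float(rng.uniform(300, 1500)), 2)
    return annotations, qual


def _alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    bases = list("ACGT")
    ref = str(rng.choice(bases))
    if not indel:
        alt = str(rng.choice([b for b in bases if b != ref]))
        return ref, alt
    if rng.random() < 0.5:  # deletion
        extra = _random_seq(rng, int(rng.integers(1, 4)))
        return ref + extra, ref
    return ref, ref + _random_seq(rng, int(rng.integers(1, 4)))


def _pileup_for_gt(rng: np.random.Generator, gt: tuple[int, int]) -> tuple[int, int]:
    depth = int(rng.integers(25, 45))
    if gt == (0, 0):
        return depth, 0
    if gt == (1, 1):
        return 0, depth
    alt = int(round(depth * rng.uniform(0.4, 0.6)))
    return depth - alt, alt


def _denovo_fetus_pileup(rng: np.random.Generator) -> tuple[int, int]:
    depth = int(rng.integers(25, 45))
    alt = int(round(depth * rng.uniform(0.38, 0.62)))
    alt = min(max(alt, int(np.ceil(0.3 * depth))), int(np.floor(0.7 * depth)))
    return depth - alt, alt


def sim_trio(config: SimConfig) -> TrioSim:
    """Trio variant table with planted de novos and single-defect artifacts.

    Inherited variants are Mendelian-consistent; planted de novo variants
    pass every downstream filter; each artifact class violates exactly
    one filter (low QUAL, low GQ, low pileup depth, parental alternate
    reads, skewed fetal allele balance, or a 5-variants-in-100-bp density
    cluster) and is otherwise a canonical de novo.
    """
    rng = _rng(config, _STREAM_TRIO)
    counts = dict(config.artifact_counts)
    n_art = sum(counts.values())
    n_inherited = config.n_variants - config.n_true_denovo - n_art

    units: list[tuple[str, int]] = []  # (category, n variants in unit)
    units += [("inherited", 1)] * n_inherited
    units += [("true_denovo", 1)] * config.n_true_denovo
    for cls, n in counts.items():
        if cls == "density_cluster":
            units += [("density_cluster", 5)] * (n // 5)
        else:
            units += [(cls, 1)] * n
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    chrom_names = list(_TRIO_CONTIGS)
    per_chrom = int(np.ceil(len(units) / len(chrom_names)))
    records: list[TrioVariantRecord] = []
    pileups: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    truth_rows = []

    for ci, chrom in enumerate(chrom_names):
        chunk = units[ci * per_chrom:(ci + 1) * per_chrom]
        pos = 10_000
        for category, width in chunk:
            if width == 1:
                pos += int(rng.integers(200, 500))
                positions = [pos]
            else:
                pos += int(rng.integers(300, 600))
                positions = [pos]
                for _ in range(width - 1):
                    positions.append(positions[-1] + int(rng.integers(5, 20)))
                pos = positions[-1]
            for p in positions:
                rec, pile, label = _make_variant(rng, config, chrom, p, category)
                records.append(rec)
                pileups[(chrom, p)] = pile
                truth_rows.append({
                    "chrom": chrom, "pos": p, "ref": rec.ref, "alt": rec.alt,
                    "category": label,
                    "var_class": rec.var_class,
                })
    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return TrioSim(records=records, pileups=pileups, truth=truth, contigs=dict(_TRIO_CONTIGS))


def _make_variant(rng, config, chrom, pos, category):
    annotations, qual = _clean_annotations(rng)
    label = category if category in ("inherited", "true_denovo") else f"artifact_{category}"

    if category == "inherited":
        ref, alt = _alleles(rng, indel=rng.random() < 0.1)
        parent_gts = [(0, 0), (0, 1), (1, 1)]
        mother = parent_gts[int(rng.integers(0, 3))]
        father = parent_gts[int(rng.integers(0, 3))]
        if mother == (0, 0) and father == (0, 0):
            father = (0, 1)
        fetus = tuple(sorted((
            mother[int(rng.integers(0, 2))], father[int(rng.integers(0, 2))]
        )))
        gts = {"mother": mother, "father": father, "fetus": fetus}
    else:
        is_indel = (
            category == "true_denovo" and rng.random() < config.denovo_indel_fraction
        )
        ref, alt = _alleles(rng, indel=is_indel)
        gts = {"mother": (0, 0), "father": (0, 0), "fetus": (0, 1)}

    pile = {role: _pileup_for_gt(rng, gt) for role, gt in gts.items()}
    if category != "inherited":
        pile["fetus"] = _denovo_fetus_pileup(rng)
    gqs = {role: 99 for role in ROLES}

    if category == "low_qual":
        qual = round(float(rng.uniform(20, 90)), 2)
    elif category == "low_gq":
        gqs[str(rng.choice(ROLES))] = int(rng.integers(5, 30))
    elif category == "low_dp":
        role = str(rng.choice(ROLES))
        depth = int(rng.integers(5, 20))
        if role == "fetus":
            alt_n = max(1, min(depth - 1, int(round(depth * 0.5))))
            pile[role] = (depth - alt_n, alt_n)
        else:
            pile[role] = (depth, 0)
    elif category == "parent_leak":
        role = str(rng.choice(["mother", "father"]))
        depth = pile[role][0]
        leak = int(rng.integers(1, 4))
        pile[role] = (depth - leak, leak)
    elif category == "allele_balance":
        depth = int(rng.integers(25, 45))
        if rng.random() < 0.5:
            ab = rng.uniform(0.02, 0.2)
        else:
            ab = rng.uniform(0.8, 0.98)
        alt_n = int(round(depth * ab))
        alt_n = min(max(alt_n, 0), depth)
        if 0.3 <= alt_n / depth <= 0.7:  # guard against rounding back into band
            alt_n = 0
        pile["fetus"] = (depth - alt_n, alt_n)

    samples = {}
    for role in ROLES:
        ref_n, alt_n = pile[role]
        samples[role] = SampleCall(
            gt=gts[role], gq=gqs[role], dp=ref_n + alt_n, ad=(ref_n, alt_n)
        )
    rec = TrioVariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
        annotations=annotations, samples=samples,
    )
    return rec, pile, label


def write_trio_vcf(sim: TrioSim, path: str) -> None:
    """Write the simulated trio as a VCF 4.2 with QD/FS/MQ/rank-sum INFO."""
    header = pysam.VariantHeader()
    for name, length in sim.contigs.items():
        header.contigs.add(name, length=length)
    for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
        header.info.add(key, 1, "Float", f"{key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for role in ROLES:
        header.add_sample(role)
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in sim.records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), qual=r.qual
            )
            for key, value in r.annotations.items():
                rec.info[key] = value
            for role in ROLES:
                call = r.samples[role]
                rec.samples[role]["GT"] = call.gt
                rec.samples[role]["AD"] = call.ad
                rec.samples[role]["DP"] = call.dp
                rec.samples[role]["GQ"] = call.gq
            out.write(rec)


def write_pileup_tsv(sim: TrioSim, path: str) -> None:
    rows = []
    for (chrom, pos), by_role in sorted(sim.pileups.items()):
        for role in ROLES:
            ref_n, alt_n = by_role[role]
            rows.append({
                "chrom": chrom, "pos": pos, "sample": role,
                "ref_count": ref_n, "alt_count": alt_n,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomes with planted off-target sites


def gen_genome_offtargets(
    config: SimConfig,
    editor: EditorSpec | str = "BE3",
    chrom: str = "synth1",
) -> tuple[dict[str, str], str, list[OfftargetSite]]:
    """Random genome with a planted on-target and mismatch off-target sites.

    One perfect (0-mismatch) on-target plus one site per entry of
    ``config.planted_mismatches``, each at the stated Hamming distance,
    strands alternating, placements non-overlapping. Returns
    ``(genome, spacer, truth_sites)``.
    """
    if isinstance(editor, str):
        editor = build_editor_spec(editor)
    rng = _rng(config, _STREAM_GENOME)
    span = editor.spacer_len + len(editor.pam)
    n_sites = len(config.planted_mismatches) + 1
    if config.genome_len < n_sites * (span + 50) + 100:
        raise ValueError("genome_len too small to pack the requested sites")
    spacer = _random_seq(rng, editor.spacer_len)
    genome = list(_random_seq(rng, config.genome_len))

    slot_width = config.genome_len // n_sites
    starts = [
        s * slot_width + int(rng.integers(10, slot_width - span - 10))
        for s in range(n_sites)
    ]
    plan = [(0, "+")] + [
        (mm, "+" if i % 2 == 0 else "-")
        for i, mm in enumerate(config.planted_mismatches)
    ]
    truth: list[OfftargetSite] = []
    for start, (n_mm, strand) in zip(starts, plan):
        proto = list(spacer)
        mm_positions = rng.choice(editor.spacer_len, size=n_mm, replace=False)
        for j in mm_positions:
            proto[j] = str(rng.choice([b for b in "ACGT" if b != proto[j]]))
        proto_str = "".join(proto)
        pam = _realize_pam(rng, editor.pam)
        block = proto_str + pam
        if strand == "-":
            block = revcomp(block)
        genome[start:start + span] = list(block)
        truth.append(
            OfftargetSite(
                chrom=chrom, start=start, end=start + span, strand=strand,
                n_mismatches=n_mm, matched_sequence=proto_str,
            )
        )
    return {chrom: "".join(genome)}, spacer, truth


# ---------------------------------------------------------------------------
# FASTA I/O for clone sets


def write_clone_fasta(clones: list[tuple[str, str]], path: str) -> None:
    """One record per clone; headers ``embryo_id|blastomere_id|clone_id``."""
    with open(path, "w") as fh:
        for clone_id, seq in clones:
            fh.write(f">{clone_id}\n{seq}\n")


def read_clone_fasta(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
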