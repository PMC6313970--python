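"""Cohort-scale synthetic study construction.

One synthetic cohort emulates the design of a matched tumor/xenograft panel
study: per case, a primary tumor sample and a passage-2 (P2) xenograft
sample sequenced over the same targeted panel against a shared toy reference
pair. The defaults encode the study conditions the pipeline is meant to
reproduce:

* 10 matched cases, mean depth 500x, 100 bp single-end reads, 1% base error
  with matching base quality 20;
* primary tumors at 60% purity (the remainder human stroma), xenografts at
  90% purity with 10% mouse stromal reads and no human stroma;
* three clones per case (truncal plus two subclones), engraftment modeled
  as a 1e5-cell multinomial bottleneck with log-normal selection weights,
  then two neutral passages to P2;
* per case: truncal SNVs (two forced into driver genes) and one truncal
  indel at a short homopolymer run, subclone-private SNVs, and
  heterozygous germline SNVs with 5% population allele frequency to
  exercise the population filter;
* a human/mouse divergence of 0.10 with two conserved 600 bp windows whose
  residual diverged positions become mouse-homology artifact alleles in the
  xenografts' relaxed datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .annotate import GeneModel
from .clonal import Clone, ClonalModel, PlantedVariant, simulate_passage
from .genome import GenomePair, make_genome_pair
from .reads import ReadSet, SampleSpec, TruthSet, simulate_reads
from .stats import PanelDefinition

PATHWAY_NAMES = ("Wnt", "MAPK", "PI3K-Akt", "VEGF", "TGF-beta")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 10
    # genome / panel
    genome_length: int = 12800
    divergence: float = 0.10
    homopolymer_enrichment: float = 1.0
    n_genes: int = 24
    gene_length: int = 500
    gene_gap: int = 25
    n_driver_genes: int = 8
    conserved_window_length: int = 600
    conserved_window_rate: float = 0.0035
    n_conserved_windows: int = 2
    # sequencing
    depth: float = 500.0
    read_length: int = 100
    base_error_rate: float = 0.01
    base_quality: int = 20
    mapq_decay: float = 10.0
    # composition (read fractions per compartment)
    primary_stromal_human: float = 0.4
    primary_stromal_mouse: float = 0.0
    pdx_stromal_human: float = 0.0
    pdx_stromal_mouse: float = 0.1
    # clonal architecture
    clone_fractions_primary: tuple[float, ...] = (0.5, 0.3, 0.2)
    n_truncal_snv: int = 6
    n_truncal_driver_snv: int = 2  # of the truncal SNVs, forced into driver genes
    n_truncal_indel: int = 1
    n_subclonal_snv: int = 3  # per subclone
    n_germline_snv: int = 3
    germline_pop_af: float = 0.05
    # passage dynamics
    bottleneck_cells: int = 100_000
    selection_sigma: float = 0.5  # log-normal sd of clone selection weights; 0 = neutral
    sample_stages: tuple[str, ...] = ("primary", "P2")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load study conditions from a YAML mapping of config fields."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("clone_fractions_primary", "sample_stages"):
            if tup in data:
                data[tup] = tuple(data[tup])
        return cls(**data)

    @classmethod
    def neutral(cls, **overrides) -> "CohortConfig":
        """Neutral passage and equal purities: the no-shift control.

        "Equal purity" refers to the purity of the human DNA compartment,
        because mouse stromal reads do not contribute depth on the human
        reference (outside conserved windows) and therefore do not dilute
        the observed allele fraction the way human stroma does. Both stages
        are pure tumor within the human compartment; the xenograft keeps
        its mouse stromal reads so host-contamination machinery stays
        exercised.
        """
        base = dict(
            selection_sigma=0.0,
            primary_stromal_human=0.0,
            primary_stromal_mouse=0.0,
            pdx_stromal_human=0.0,
            pdx_stromal_mouse=0.1,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Case:
    case_id: str
    model: ClonalModel  # with fractions for every simulated stage
    selection_weights: np.ndarray


@dataclass
class Cohort:
    """A fully simulated cohort plus every ground-truth table."""

    config: CohortConfig
    seed: int
    genomes: GenomePair
    panel: PanelDefinition
    gene_models: list[GeneModel]
    driver_genes: set[str]
    pathway_map: dict[str, list[str]]
    cases: list[Case]
    readsets: dict[str, ReadSet]
    truths: dict[str, TruthSet]
    pairing: list[tuple[str, str]]  # (primary sample id, xenograft sample id)
    sample_class: dict[str, str]
    pop_af_table: dict
    artifact_keys: set

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.readsets)

    def truncal_variant_ids(self, case: Case) -> list[str]:
        n_clones = len(case.model.clones)
        return [
            v.variant_id
            for v in case.model.variants
            if not v.germline and len(case.model.carriers(v.variant_id)) == n_clones
        ]

    def germline_keys(self) -> set:
        return set(self.pop_af_table)


def _find_short_runs(seq: str, lo: int, hi: int, min_len=3, max_len=4) -> list[tuple[int, int]]:
    """(start, length) of maximal homopolymer runs of length 3-4 in [lo, hi)."""
    runs = []
    i = lo
    while i < hi:
        j = i
        while j + 1 < hi and seq[j + 1] == seq[i]:
            j += 1
        length = j - i + 1
        if min_len <= length <= max_len:
            # also require the run not to extend a same-base neighbour
            if (i == 0 or seq[i - 1] != seq[i]) and (j + 1 >= len(seq) or seq[j + 1] != seq[i]):
                runs.append((i, length))
        i = j + 1
    return runs


def _pick_positions(rng, pool: np.ndarray, n: int, used: set, min_gap: int = 12) -> list[int]:
    out: list[int] = []
    candidates = rng.permutation(pool)
    for pos in candidates:
        pos = int(pos)
        if all(abs(pos - u) >= min_gap for u in used):
            out.append(pos)
            used.add(pos)
            if len(out) == n:
                return out
    raise RuntimeError("could not place variants: position pool exhausted")


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Build genomes, panel, cases, reads and truth for one cohort."""
    cfg = config or CohortConfig()
    master = np.random.default_rng(seed)

    # --- genome with conserved (low-divergence) windows inside the panel
    G, L = cfg.genome_length, cfg.read_length
    regions: list[tuple[int, int, str]] = []
    start = max(L, 100)
    for i in range(cfg.n_genes):
        end = start + cfg.gene_length
        if end > G - L:
            raise ValueError("panel does not fit in the genome; increase genome_length")
        regions.append((start, end, f"GENE{i:02d}"))
        start = end + cfg.gene_gap
    span = regions[-1][1] - regions[0][0]
    windows = []
    for w in range(cfg.n_conserved_windows):
        w_start = regions[0][0] + int((w + 0.35) * span / max(cfg.n_conserved_windows, 1))
        windows.append((w_start, w_start + cfg.conserved_window_length, cfg.conserved_window_rate))
    genomes = make_genome_pair(
        G,
        cfg.divergence,
        homopolymer_enrichment=cfg.homopolymer_enrichment,
        seed=int(master.integers(0, 2**31 - 1)),
        low_divergence_windows=windows,
    )
    contig = genomes.contig_name_human

    gene_models = [GeneModel(name, s, e) for s, e, name in regions]
    panel = PanelDefinition.from_regions(regions)
    drivers = {m.name for m in gene_models[: cfg.n_driver_genes]}
    pathway_map = {
        name: [PATHWAY_NAMES[i % len(PATHWAY_NAMES)]]
        + ([PATHWAY_NAMES[(i + 2) % len(PATHWAY_NAMES)]] if i % 3 == 0 else [])
        for i, name in enumerate(sorted(drivers))
    }

    # position pools: inside targets, away from conserved windows and genome ends
    tmask = np.zeros(G, dtype=bool)
    for s, e, _ in regions:
        tmask[s:e] = True
    in_window = np.zeros(G, dtype=bool)
    for w_start, w_end, _ in windows:
        in_window[w_start:w_end] = True
    usable = tmask & ~in_window
    usable[: L] = False
    usable[G - L - 8 :] = False
    snv_pool = np.flatnonzero(usable)
    driver_mask = np.zeros(G, dtype=bool)
    for m in gene_models:
        if m.name in drivers:
            driver_mask[m.start : m.end] = True
    driver_pool = np.flatnonzero(usable & driver_mask)

    human_seq = genomes.human_seq
    run_sites = [
        (rs, rl)
        for rs, rl in _find_short_runs(human_seq, L, G - L - 8)
        if usable[rs] and rs > 0
    ]
    master.shuffle(run_sites)
    run_iter = iter(run_sites)

    gene_of = np.full(G, -1)
    for gi, m in enumerate(gene_models):
        gene_of[m.start : m.end] = gi

    def _gene_name(pos0: int) -> str | None:
        gi = gene_of[pos0]
        return gene_models[gi].name if gi >= 0 else None

    used_positions: set[int] = set()
    cases: list[Case] = []
    readsets: dict[str, ReadSet] = {}
    truths: dict[str, TruthSet] = {}
    pairing = []
    sample_class: dict[str, str] = {}
    pop_af: dict = {}

    def _snv(vid, pos0, germline=False, pop=None):
        ref = human_seq[pos0]
        alt_choices = [b for b in "ACGT" if b != ref]
        alt = alt_choices[int(master.integers(0, 3))]
        gene = _gene_name(pos0)
        return PlantedVariant(
            variant_id=vid, pos0=pos0, ref=ref, alt=alt, vtype="SNP",
            gene=gene, is_driver=bool(gene in drivers), germline=germline,
            pop_af=pop, contig=contig,
        )

    for ci in range(cfg.n_cases):
        case_id = f"case{ci:02d}"
        variants: list[PlantedVariant] = []

        n_plain = cfg.n_truncal_snv - cfg.n_truncal_driver_snv
        d_pos = _pick_positions(master, driver_pool, cfg.n_truncal_driver_snv, used_positions)
        t_pos = _pick_positions(master, snv_pool, n_plain, used_positions)
        truncal_ids = []
        for k, pos0 in enumerate(d_pos + t_pos):
            vid = f"{case_id}_trunk{k}"
            variants.append(_snv(vid, pos0))
            truncal_ids.append(vid)

        for k in range(cfg.n_truncal_indel):
            placed = False
            for run_start, run_len in run_iter:
                anchor = run_start - 1
                if any(abs(anchor - u) < L + 10 for u in used_positions):
                    continue
                ref = human_seq[anchor] + human_seq[run_start]
                if ref[0] == ref[1]:
                    continue  # anchor must not extend the run
                used_positions.add(anchor)
                vid = f"{case_id}_indel{k}"
                gene = _gene_name(anchor)
                variants.append(
                    PlantedVariant(
                        variant_id=vid, pos0=anchor, ref=ref, alt=ref[0], vtype="indel",
                        gene=gene, is_driver=bool(gene in drivers), contig=contig,
                    )
                )
                truncal_ids.append(vid)
                placed = True
                break
            if not placed:
                raise RuntimeError("ran out of homopolymer runs for indel placement")

        sub_ids: list[list[str]] = [[], []]
        for clone_no in (1, 2):
            for k in range(cfg.n_subclonal_snv):
                pos0 = _pick_positions(master, snv_pool, 1, used_positions)[0]
                vid = f"{case_id}_sub{clone_no}_{k}"
                variants.append(_snv(vid, pos0))
                sub_ids[clone_no - 1].append(vid)

        for k in range(cfg.n_germline_snv):
            pos0 = _pick_positions(master, snv_pool, 1, used_positions)[0]
            vid = f"{case_id}_germ{k}"
            v = _snv(vid, pos0, germline=True, pop=cfg.germline_pop_af)
            variants.append(v)
            pop_af[v.key] = cfg.germline_pop_af

        fracs = cfg.clone_fractions_primary
        clones = [
            Clone("cl_trunk", tuple(truncal_ids), {"primary": fracs[0]}),
            Clone("cl_sub1", tuple(truncal_ids + sub_ids[0]), {"primary": fracs[1]}),
            Clone("cl_sub2", tuple(truncal_ids + sub_ids[1]), {"primary": fracs[2]}),
        ]
        model = ClonalModel(
            case_id=case_id,
            clones=clones,
            variants=variants,
            stromal_human_fraction={"primary": cfg.primary_stromal_human},
            stromal_mouse_fraction={"primary": cfg.primary_stromal_mouse},
        )

        if cfg.selection_sigma > 0:
            weights = np.exp(master.normal(0.0, cfg.selection_sigma, size=len(clones)))
        else:
            weights = np.ones(len(clones))
        stage_chain = [("primary", "P0", weights), ("P0", "P1", None), ("P1", "P2", None)]
        for s_from, s_to, w in stage_chain:
            model = simulate_passage(
                model, s_from, s_to,
                bottleneck_cells=cfg.bottleneck_cells,
                selection_weights=w,
                seed=int(master.integers(0, 2**31 - 1)),
                stromal_human_fraction=cfg.pdx_stromal_human,
                stromal_mouse_fraction=cfg.pdx_stromal_mouse,
            )
        cases.append(Case(case_id=case_id, model=model, selection_weights=np.asarray(weights)))

        stage_ids = {}
        for stage in cfg.sample_stages:
            spec = SampleSpec(
                stage=stage, depth=cfg.depth, read_length=L,
                base_error_rate=cfg.base_error_rate, base_quality=cfg.base_quality,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            sample_id = f"{case_id}_{'PT' if stage == 'primary' else stage}"
            rs, truth = simulate_reads(
                genomes, model, spec, sample_id=sample_id,
                targets=[(s, e) for s, e, _ in regions], mapq_decay=cfg.mapq_decay,
            )
            readsets[sample_id] = rs
            truths[sample_id] = truth
            stage_ids[stage] = sample_id
            sample_class[sample_id] = "primary" if stage == "primary" else "PDX_P2"
        if "primary" in stage_ids and "P2" in stage_ids:
            pairing.append((stage_ids["primary"], stage_ids["P2"]))

    artifact_keys = set()
    for w_start, w_end, _ in windows:
        for pos0 in genomes.diverged_positions(w_start, w_end):
            pos0 = int(pos0)
            if tmask[pos0]:
                artifact_keys.add((contig, pos0 + 1, human_seq[pos0], genomes.mouse_seq[pos0]))

    return Cohort(
        config=cfg, seed=seed, genomes=genomes, panel=panel,
        gene_models=gene_models, driver_genes=drivers, pathway_map=pathway_map,
        cases=cases, readsets=readsets, truths=truths, pairing=pairing,
        sample_class=sample_class, pop_af_table=pop_af, artifact_keys=artifact_keys,
    )
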