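"""End-to-end orchestration: simulate -> filter -> spectra -> normalize -> compare.

A :class:`RunConfig` names either a simulation to generate or existing
inputs (VCF + FASTA + compartment BEDs + panel table), plus analysis
parameters.  :func:`run_pipeline` executes the stages in order, writes
every artifact under the output directory, and records a manifest with
SHA-256 checksums and the resolved configuration, so identical configs
and seeds yield identical manifests.  A stage whose inputs and recorded
outputs are unchanged since the previous run is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .compartments import GenomicCompartment, compartment_content
from .filtering import PanelMetadata, polarize_and_filter, write_dispositions
from .normalize import rescale_rates
from .simulate import SimulationConfig, simulate_panel
from .spectra import (
    SpectrumVector,
    individual_spectrum,
    randomized_spectrum,
    sites_in_compartment,
    species_spectrum,
    write_spectra,
)
from .stats import (
    build_spectrum_matrix,
    bootstrap_enrichment_test,
    heatmap_correlation,
    log_odds_heatmap,
    pairwise_distance_distributions,
    run_nmf,
    run_pca,
)

log = logging.getLogger("apespectra")


@dataclasses.dataclass
class RunConfig:
    outdir: Path
    seed: int
    simulation: SimulationConfig | None = None
    vcf: Path | None = None
    fasta: Path | None = None
    panel_table: Path | None = None
    compartment_beds: dict[str, Path] = dataclasses.field(default_factory=dict)
    stages: tuple[str, ...] = (
        "simulate", "filter", "spectra", "normalize", "pca", "nmf",
        "distances", "heatmap",
    )
    mode: str = "randomized"  # full | randomized | doubletons
    context_order: int = 3
    reference_compartment: str | None = None
    nmf_k: int = 6
    nmf_restarts: int = 20
    bootstrap_reps: int = 100
    bootstrap_target: str | None = None
    bootstrap_background: str | None = None
    bootstrap_class: str | None = None
    hwe_alpha: float = 0.05
    missingness_threshold: float = 0.0

    def validate(self) -> None:
        if self.mode not in ("full", "randomized", "doubletons"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.simulation is None:
            for p in (self.vcf, self.fasta, self.panel_table):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input missing: {p}")
            for p in self.compartment_beds.values():
                if not Path(p).exists():
                    raise FileNotFoundError(f"compartment BED missing: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "manifest.json"
        self.previous = {}
        if self.path.exists():
            try:
                self.previous = json.loads(self.path.read_text()).get("stages", {})
            except json.JSONDecodeError:
                self.previous = {}
        self.data = {"config": _jsonable(config), "seed": config.seed, "stages": {}}

    def stage_cached(self, name: str, inputs: list[Path]) -> bool:
        prev = self.previous.get(name)
        if not prev:
            return False
        in_sums = {str(p): _sha256(Path(p)) for p in inputs}
        if prev.get("inputs") != in_sums:
            return False
        for p, sum_ in prev.get("outputs", {}).items():
            if not Path(p).exists() or _sha256(Path(p)) != sum_:
                return False
        self.data["stages"][name] = prev
        return True

    def record(self, name: str, inputs: list[Path], outputs: list[Path], info=None):
        self.data["stages"][name] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "info": _jsonable(info or {}),
        }

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    rng = np.random.Generator(np.random.Philox([config.seed, 0xA9E5]))

    # ---- simulate ---------------------------------------------------------
    if config.simulation is not None and "simulate" in config.stages:
        simdir = outdir / "sim"
        if manifest.stage_cached("simulate", []):
            log.info("simulate: unchanged inputs, re-using cached outputs")
            import pyfaidx

            config.vcf = simdir / "panel.vcf"
            config.fasta = simdir / "reference.fa"
            config.panel_table = simdir / "panel.tsv"
            config.compartment_beds = {
                p.stem.removeprefix("compartment_"): p
                for p in sorted(simdir.glob("compartment_*.bed"))
            }
            reference = pyfaidx.Fasta(str(config.fasta))
            panel = PanelMetadata.from_tsv(config.panel_table)
            compartments = {
                name: GenomicCompartment.from_bed(p, name)
                for name, p in config.compartment_beds.items()
            }
        else:
            sim = simulate_panel(config.simulation, simdir)
            config.vcf, config.fasta, config.panel_table = sim.vcf, sim.fasta, sim.panel_table
            config.compartment_beds = dict(sim.beds)
            manifest.record(
                "simulate", [], [sim.vcf, sim.fasta, sim.panel_table, sim.truth_json,
                                 *sim.beds.values()],
                {"n_variants": len(sim.truth.records)},
            )
            reference = sim.sequences
            panel = sim.panel
            compartments = sim.compartments
    else:
        import pyfaidx

        reference = pyfaidx.Fasta(str(config.fasta))
        panel = PanelMetadata.from_tsv(config.panel_table)
        compartments = {
            name: GenomicCompartment.from_bed(p, name)
            for name, p in config.compartment_beds.items()
        }
    if config.simulation is not None and "simulate" not in config.stages:
        raise ValueError("a simulation config requires the simulate stage")

    if set(config.stages) <= {"simulate"}:
        manifest.write()
        return manifest.data

    ref_comp_name = config.reference_compartment or next(iter(compartments), None)

    # ---- filter -----------------------------------------------------------
    kept, dispositions, tally = polarize_and_filter(
        config.vcf, panel, reference,
        use_doubletons_only=(config.mode == "doubletons"),
        context_order=config.context_order,
        missingness_threshold=config.missingness_threshold,
        hwe_alpha=config.hwe_alpha,
    )
    disp_path = outdir / "dispositions.tsv"
    write_dispositions(dispositions, disp_path)
    log.info("filter tallies: kept=%d %s", len(kept), tally)
    manifest.record(
        "filter", [Path(config.vcf), Path(config.panel_table)], [disp_path],
        {"kept": len(kept), "excluded": tally},
    )

    # ---- spectra ----------------------------------------------------------
    randomize = config.mode in ("randomized", "doubletons")
    comp_sites = {name: sites_in_compartment(kept, comp)
                  for name, comp in compartments.items()}
    species_specs: dict[str, dict[str, SpectrumVector]] = {}
    indiv_specs: dict[str, dict[str, SpectrumVector]] = {}
    spectra_paths = []
    for name, sites in comp_sites.items():
        species_specs[name] = {
            sp: species_spectrum(sites, panel, sp, config.context_order, name)
            for sp in panel.species
        }
        if randomize:
            indiv_specs[name] = randomized_spectrum(
                sites, panel, rng, config.context_order, name
            )
        else:
            indiv_specs[name] = {
                s: individual_spectrum(sites, s, panel, config.context_order, name)
                for s in panel.samples
            }
        p_sp = outdir / f"spectra_species_{name}.tsv"
        write_spectra(list(species_specs[name].values()), p_sp, config.seed)
        p_in = outdir / f"spectra_individual_{name}.tsv"
        write_spectra(list(indiv_specs[name].values()), p_in, config.seed)
        spectra_paths += [p_sp, p_in]
    if "spectra" in config.stages:
        manifest.record(
            "spectra", [disp_path], spectra_paths,
            {"mode": config.mode, "sites_per_compartment":
             {n: len(s) for n, s in comp_sites.items()}},
        )

    # ---- normalize --------------------------------------------------------
    contents = {
        name: compartment_content(reference, comp, config.context_order)
        for name, comp in compartments.items()
    }
    rescaled_indiv = {}
    rescaled_species = {}
    if "normalize" in config.stages and ref_comp_name is not None:
        ref_content = contents[ref_comp_name]
        rate_rows = []
        for name in compartments:
            rescaled_species[name] = {
                sp: rescale_rates(v, contents[name], ref_content)
                for sp, v in species_specs[name].items()
                if v.total > 0
            }
            rescaled_indiv[name] = {
                s: rescale_rates(v, contents[name], ref_content)
                for s, v in indiv_specs[name].items()
                if v.total > 0
            }
            for sp, rr in rescaled_species[name].items():
                rate_rows.append(pd.Series(rr.rates, name=f"{sp}|{name}"))
        rates_path = outdir / "rescaled_species_rates.tsv"
        pd.DataFrame(rate_rows).T.set_axis(
            list(catalog.classes(config.context_order))
        ).to_csv(rates_path, sep="\t", index_label="class")
        manifest.record("normalize", spectra_paths, [rates_path],
                        {"reference": ref_comp_name})

    # ---- PCA --------------------------------------------------------------
    if "pca" in config.stages:
        rows = []
        if rescaled_indiv:
            for name in compartments:
                rows += list(rescaled_indiv[name].values())
        else:
            for name in compartments:
                rows += [v.frequencies() for v in indiv_specs[name].values()
                         if v.total > 0]
        mat = build_spectrum_matrix(rows)
        pca = run_pca(mat)
        scores_path = outdir / "pca_scores.tsv"
        loadings_path = outdir / "pca_loadings.tsv"
        var_path = outdir / "pca_variance.tsv"
        pca.scores.to_csv(scores_path, sep="\t")
        pca.loadings.to_csv(loadings_path, sep="\t")
        pd.Series(
            pca.variance_fractions,
            index=[f"PC{i + 1}" for i in range(len(pca.variance_fractions))],
            name="variance_fraction",
        ).to_csv(var_path, sep="\t")
        manifest.record("pca", spectra_paths, [scores_path, loadings_path, var_path],
                        {"variance_fractions": pca.variance_fractions[:10]})

    # ---- NMF --------------------------------------------------------------
    if "nmf" in config.stages:
        rows = []
        for name in compartments:
            rows += [v for v in indiv_specs[name].values() if v.total > 0]
        mat = build_spectrum_matrix(rows)
        nmf_rng = np.random.Generator(np.random.Philox([config.seed, 0x17F]))
        k = min(config.nmf_k, mat.shape[0] - 1, mat.shape[1] - 1)
        sigset = run_nmf(mat, k, config.nmf_restarts, nmf_rng)
        sig_path = outdir / "nmf_signatures.tsv"
        exp_path = outdir / "nmf_exposures.tsv"
        sigset.signatures.to_csv(sig_path, sep="\t")
        sigset.exposures.to_csv(exp_path, sep="\t")
        manifest.record("nmf", spectra_paths, [sig_path, exp_path],
                        {"k": k, "residual": sigset.residual})

    # ---- distances --------------------------------------------------------
    if "distances" in config.stages and ref_comp_name is not None:
        specs = [v for v in indiv_specs[ref_comp_name].values() if v.total > 0]
        within, between = pairwise_distance_distributions(
            specs, panel.species_of
        )
        dist_path = outdir / "distances.tsv"
        rows = [
            {"kind": "within", "a": g, "b": g, "distance": d}
            for g, ds in within.items() for d in ds
        ] + [
            {"kind": "between", "a": a, "b": b, "distance": d}
            for (a, b), ds in between.items() for d in ds
        ]
        pd.DataFrame(rows).to_csv(dist_path, sep="\t", index=False)
        manifest.record("distances", spectra_paths, [dist_path], {})

    # ---- log-odds heatmaps ------------------------------------------------
    if "heatmap" in config.stages and rescaled_species and ref_comp_name is not None:
        heat_rows = {}
        heatmaps = {}
        for name in compartments:
            if name == ref_comp_name:
                continue
            for sp in panel.species:
                if sp in rescaled_species.get(name, {}) and sp in rescaled_species.get(
                    ref_comp_name, {}
                ):
                    hm = log_odds_heatmap(
                        rescaled_species[name][sp],
                        rescaled_species[ref_comp_name][sp],
                        species=sp,
                    )
                    heatmaps[(name, sp)] = hm
                    heat_rows[f"{sp}|{name}_vs_{ref_comp_name}"] = hm.values
        heat_path = outdir / "log_odds_heatmaps.tsv"
        pd.DataFrame(heat_rows, index=list(catalog.classes(config.context_order))).to_csv(
            heat_path, sep="\t", index_label="class"
        )
        corr_rows = []
        names = sorted({n for n, _ in heatmaps})
        for name in names:
            spp = sorted({sp for n, sp in heatmaps if n == name})
            for i, a in enumerate(spp):
                for b in spp[i + 1 :]:
                    try:
                        r, p = heatmap_correlation(heatmaps[(name, a)], heatmaps[(name, b)])
                        corr_rows.append(
                            {"comparison": name, "species_a": a, "species_b": b,
                             "pearson_r": r, "p_value": p}
                        )
                    except ValueError:
                        continue
        corr_path = outdir / "heatmap_correlations.tsv"
        pd.DataFrame(corr_rows).to_csv(corr_path, sep="\t", index=False)
        manifest.record("heatmap", spectra_paths, [heat_path, corr_path], {})

    # ---- bootstrap enrichment --------------------------------------------
    if (
        "bootstrap-erv" in config.stages
        and config.bootstrap_target
        and config.bootstrap_background
        and config.bootstrap_class
    ):
        from .compartments import bootstrap_ervlike

        target = compartments[config.bootstrap_target]
        background = compartments[config.bootstrap_background]
        boot_rng = np.random.Generator(np.random.Philox([config.seed, 0xB007]))
        reps = bootstrap_ervlike(
            target, background, reference, config.bootstrap_reps, boot_rng
        )
        cls_idx = catalog.class_index(config.context_order)[config.bootstrap_class]

        def pooled(sites, comp_name):
            vals = np.zeros(len(catalog.classes(config.context_order)))
            for snv in sites:
                from .spectra import site_class

                vals[site_class(snv, config.context_order)] += 1
            return SpectrumVector(vals, config.context_order, "count",
                                  {"id": "pooled", "compartment": comp_name})

        t_sites = comp_sites[config.bootstrap_target]
        b_sites = comp_sites[config.bootstrap_background]
        rep_specs, rep_contents = [], []
        for i, rep in enumerate(reps):
            rep_specs.append(pooled(sites_in_compartment(kept, rep), f"rep{i}"))
            rep_contents.append(
                compartment_content(reference, rep, config.context_order)
            )
        result = bootstrap_enrichment_test(
            pooled(t_sites, config.bootstrap_target),
            pooled(b_sites, config.bootstrap_background),
            contents[config.bootstrap_target],
            contents[config.bootstrap_background],
            cls_idx,
            rep_specs,
            rep_contents,
            boot_rng,
        )
        boot_path = outdir / "bootstrap_enrichment.json"
        boot_path.write_text(json.dumps(_jsonable(dataclasses.asdict(result)), indent=1))
        manifest.record("bootstrap-erv", spectra_paths, [boot_path],
                        {"observed": result.observed, "outside_null": result.outside_null})

    manifest.write()
    return manifest.data
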