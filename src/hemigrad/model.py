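"""Model-style front end: build the analysis from data, fit, inspect results.

``GradientAsymmetryAnalysis`` holds the data (parcellated time series,
phenotype, homotopic parcellation) and the analysis parameters;
``fit()`` runs QC -> FC -> hemispheric gradients -> Procrustes alignment ->
asymmetry indices -> ComBat harmonization -> mass-univariate group
statistics, and returns a ``GradientAsymmetryResults`` carrying the feature
tables, comparison results, effect-size maps and diagnostics, with
``summary()`` and prediction methods hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asymmetry, connectome, gradients, stats
from .combat import harmonize, make_design
from .exceptions import DataError, SelectionError
from .parcellation import ParcellationInfo
from .prediction import classify_nested_cv, regress_nested_cv, select_features
from .simulate import SimulatedStudy, subjects_to_frame


@dataclass
class AnalysisParams:
    """Tunable parameters of the gradient-asymmetry pipeline."""

    density: float = gradients.DEFAULT_DENSITY
    alpha: float = gradients.DEFAULT_ALPHA
    diffusion_time: float = gradients.DEFAULT_DIFFUSION_TIME
    n_components: int = gradients.DEFAULT_N_COMPONENTS
    n_gradients: int = asymmetry.DEFAULT_N_GRADIENTS
    mean_fd_max: float = connectome.MEAN_FD_MAX
    max_fd_max: float = connectome.MAX_FD_MAX
    q_level: float = stats.DEFAULT_Q_LEVEL
    covariates: tuple = stats.DEFAULT_COVARIATES
    harmonize: bool = True


class GradientAsymmetryAnalysis:
    """Hemispheric gradient-asymmetry case-control analysis.

    Parameters
    ----------
    timeseries
        Mapping subject_id -> (regions x timepoints) array, region order
        matching the parcellation.
    phenotype
        Table with subject_id, group, age, sex, site, mean_fd, max_fd and
        optional PANSS columns.
    parcellation
        Homotopic parcellation covering the time-series rows.
    sign_reference
        Optional (n_per_hemi,) or (n_per_hemi, k) array fixing template
        column signs (e.g. planted loadings for synthetic studies).
    """

    def __init__(
        self,
        timeseries: dict[str, np.ndarray],
        phenotype: pd.DataFrame,
        parcellation: ParcellationInfo,
        params: AnalysisParams | None = None,
        sign_reference: np.ndarray | None = None,
    ) -> None:
        self.timeseries = timeseries
        self.phenotype = phenotype.reset_index(drop=True)
        self.parcellation = parcellation
        self.params = params or AnalysisParams()
        self.sign_reference = sign_reference
        missing = set(self.phenotype["subject_id"]) - set(timeseries)
        if missing:
            raise DataError(f"no time series for subject(s) {sorted(missing)[:5]}")

    @classmethod
    def from_study(cls, study: SimulatedStudy,
                   params: AnalysisParams | None = None,
                   use_truth_reference: bool = True) -> "GradientAsymmetryAnalysis":
        """Build from a simulated study, orienting templates by the planted
        loadings so recovered gradients carry the ground-truth sign."""
        ref = study.truth.axis_loadings if use_truth_reference else None
        return cls(study.timeseries, subjects_to_frame(study.subjects),
                   study.parcellation, params, sign_reference=ref)

    @classmethod
    def from_directory(cls, path, params: AnalysisParams | None = None):
        from .io import read_study
        parcellation, phenotype, series, truth = read_study(path)
        ref = truth.axis_loadings if truth is not None else None
        return cls(series, phenotype, parcellation, params, sign_reference=ref)

    # ------------------------------------------------------------------
    def fit(self, reference_group: str = "HC") -> "GradientAsymmetryResults":
        """Run the full analysis and return the results object.

        Gradient templates are embedded from the group-average blocks of the
        ``reference_group`` subjects that survive QC ("all" uses everyone).
        """
        p = self.params
        from .io import phenotype_to_subjects
        subjects = phenotype_to_subjects(self.phenotype)
        kept, exclusions = connectome.qc_filter(subjects, p.mean_fd_max, p.max_fd_max)
        if not kept:
            raise DataError("no subjects survive motion QC")
        pheno = self.phenotype[self.phenotype["subject_id"].isin(
            [s.subject_id for s in kept])].reset_index(drop=True)

        blocks = {}
        for s in kept:
            fc = connectome.compute_fc(self.timeseries[s.subject_id])
            blocks[s.subject_id] = connectome.split_hemispheric(fc, self.parcellation)

        ref_ids = [s.subject_id for s in kept
                   if reference_group == "all" or s.group == reference_group]
        if not ref_ids:
            raise DataError(f"no reference subjects in group {reference_group!r}")
        # small parcellations cannot support the default component count
        nh = len(self.parcellation.left_indices)
        n_comp = min(p.n_components, nh - 2)
        if n_comp < p.n_gradients:
            raise DataError(
                f"{nh} regions per hemisphere support at most {nh - 2} "
                f"components; need >= {p.n_gradients}")
        intra_t, inter_t = gradients.build_templates(
            [blocks[i] for i in ref_ids], p.density, p.alpha, p.diffusion_time,
            n_comp, sign_reference=self.sign_reference,
            reference_label=f"group-average {reference_group} (n={len(ref_ids)})")

        region_maps, network_maps, grads = {}, {}, {}
        for s in kept:
            g = gradients.subject_gradients(
                blocks[s.subject_id], intra_t, inter_t, p.density, p.alpha,
                p.diffusion_time, n_comp, subject_id=s.subject_id)
            grads[s.subject_id] = g
            region_maps[s.subject_id] = asymmetry.compute_ai(
                g, self.parcellation, p.n_gradients)
            network_maps[s.subject_id] = asymmetry.network_ai(
                g, self.parcellation, p.n_gradients)
        region_features = asymmetry.cohort_ai_table(region_maps)
        network_features = asymmetry.cohort_ai_table(network_maps)

        notes = []
        multi_site = pheno["site"].nunique() > 1
        if p.harmonize and multi_site:
            design = make_design(pheno, p.covariates, include_group=True)
            region_h, _ = harmonize(region_features, pheno["site"], design)
            network_h, _ = harmonize(network_features, pheno["site"], design)
            region_features_h = pd.DataFrame(region_h, index=region_features.index,
                                             columns=region_features.columns)
            network_features_h = pd.DataFrame(network_h, index=network_features.index,
                                              columns=network_features.columns)
        else:
            if p.harmonize and not multi_site:
                notes.append("single site: harmonization skipped")
            region_features_h = region_features
            network_features_h = network_features

        network_results = stats.group_compare(
            network_features_h, pheno, family="network_all",
            covariates=p.covariates, q_level=p.q_level)
        region_tables = []
        for g_idx in range(1, p.n_gradients + 1):
            for kind in asymmetry.AI_TYPES:
                cols = [c for c in region_features_h.columns
                        if c.startswith(f"G{g_idx}_{kind}_")]
                res = stats.group_compare(
                    region_features_h[cols], pheno,
                    family=f"region_G{g_idx}_{kind}",
                    covariates=p.covariates, q_level=p.q_level)
                t = res.table.copy()
                t["family"] = res.family
                region_tables.append(t)
        region_results = stats.ComparisonResult(
            table=pd.concat(region_tables, ignore_index=True),
            family="region_per_gradient_type", q_level=p.q_level)

        d_map = stats.cohens_d_map(region_features_h, pheno, p.q_level)
        demographics = stats.demographic_tests(pheno)
        try:
            selected = select_features(network_results, region_results)
        except SelectionError as exc:
            selected = []
            notes.append(str(exc))

        return GradientAsymmetryResults(
            model=self, phenotype=pheno, exclusions=exclusions,
            intra_template=intra_t, inter_template=inter_t,
            subject_gradients=grads,
            region_features=region_features, network_features=network_features,
            region_features_harmonized=region_features_h,
            network_features_harmonized=network_features_h,
            network_results=network_results, region_results=region_results,
            cohens_d=d_map, demographics=demographics,
            selected_features=selected, notes=notes,
        )


@dataclass
class GradientAsymmetryResults:
    """Fitted pipeline outputs: features, statistics and diagnostics."""

    model: GradientAsymmetryAnalysis
    phenotype: pd.DataFrame
    exclusions: list
    intra_template: gradients.GradientTemplate
    inter_template: gradients.GradientTemplate
    subject_gradients: dict
    region_features: pd.DataFrame
    network_features: pd.DataFrame
    region_features_harmonized: pd.DataFrame
    network_features_harmonized: pd.DataFrame
    network_results: stats.ComparisonResult
    region_results: stats.ComparisonResult
    cohens_d: stats.CohensDMap
    demographics: pd.DataFrame
    selected_features: list[str]
    notes: list[str] = field(default_factory=list)

    # -- feature access -------------------------------------------------
    def feature_matrix(self, features: list[str] | None = None) -> pd.DataFrame:
        """Unharmonized selected features (prediction harmonizes per split)."""
        feats = features if features is not None else self.selected_features
        all_feats = pd.concat([self.network_features, self.region_features], axis=1)
        return all_feats[feats]

    # -- prediction -----------------------------------------------------
    def predict_diagnosis(self, n_repeats: int = 100, seed: int = 0, **kwargs):
        """Classify SZ vs HC from the selected AI features (nested CV)."""
        X = self.feature_matrix()
        y = (self.phenotype.set_index("subject_id").loc[X.index, "group"]
             == "SZ").astype(int).to_numpy()
        site = self._sites(X.index)
        return classify_nested_cv(X.to_numpy(), y, site=site,
                                  covars=self._covars(X.index),
                                  n_repeats=n_repeats, seed=seed, **kwargs)

    def predict_panss(self, scale: str = "panss_pos", n_repeats: int = 100,
                      seed: int = 0, **kwargs):
        """Predict a PANSS scale for the SZ subgroup (ridge, nested CV)."""
        pheno = self.phenotype.set_index("subject_id")
        sz_ids = pheno.index[(pheno["group"] == "SZ") & pheno[scale].notna()]
        X = self.feature_matrix().loc[sz_ids]
        y = pheno.loc[sz_ids, scale].to_numpy(dtype=float)
        return regress_nested_cv(X.to_numpy(), y, site=self._sites(sz_ids),
                                 covars=self._covars(sz_ids),
                                 n_repeats=n_repeats, seed=seed, **kwargs)

    def _sites(self, index):
        pheno = self.phenotype.set_index("subject_id").loc[index]
        return pheno["site"].to_numpy() if pheno["site"].nunique() > 1 else None

    def _covars(self, index):
        pheno = self.phenotype.set_index("subject_id").loc[index].reset_index()
        return make_design(pheno, self.model.params.covariates)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        pheno = self.phenotype
        n_hc = int((pheno["group"] == "HC").sum())
        n_sz = int((pheno["group"] == "SZ").sum())
        lines = [
            "Hemispheric gradient asymmetry analysis",
            "=" * 48,
            f"subjects after QC : {len(pheno)} ({n_hc} HC / {n_sz} SZ), "
            f"{pheno['site'].nunique()} site(s)",
            f"excluded by QC    : {len(self.exclusions)}",
            f"regions           : {self.model.parcellation.n_regions} "
            f"({len(self.model.parcellation.networks)} networks)",
            f"gradients used    : {self.model.params.n_gradients} "
            f"(of {self.model.params.n_components} computed)",
            "template expl.var : intra "
            + "/".join(f"{v:.3f}" for v in
                       self.intra_template.explained_variance[:3])
            + ", inter "
            + "/".join(f"{v:.3f}" for v in
                       self.inter_template.explained_variance[:3]),
            "",
            "Demographics:",
            self.demographics.to_string(index=False,
                                        float_format=lambda x: f"{x:.3f}"),
            "",
            f"network tests     : {len(self.network_results.table)} "
            f"({len(self.network_results.significant_features)} significant "
            f"at q<{self.network_results.q_level})",
            f"region tests      : {len(self.region_results.table)} "
            f"({len(self.region_results.significant_features)} significant)",
            f"selected features : {len(self.selected_features)}",
        ]
        sig = self.network_results.table[self.network_results.table["significant"]]
        if len(sig):
            lines += ["", "Significant network-level effects (positive t = "
                          "higher AI in SZ):",
                      sig[["feature", "t", "p", "q"]].to_string(
                          index=False, float_format=lambda x: f"{x:.4f}")]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_network_t(self, ax=None):
        """Heatmap of network-level group-difference t values (matplotlib)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        tab = self.network_results.table.copy()
        parts = tab["feature"].str.split("_", n=3, expand=True)
        tab["grad"], tab["kind"], tab["net"] = (parts[0], parts[1], parts[3])
        grid = tab.pivot_table(index="net", columns=["grad", "kind"], values="t")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(grid.to_numpy(), cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(grid.shape[1]),
                      ["_".join(c) for c in grid.columns], rotation=45, ha="right")
        ax.set_yticks(range(grid.shape[0]), grid.index)
        ax.figure.colorbar(im, ax=ax, label="t (SZ - HC)")
        ax.set_title("Network-level AI group differences")
        return ax
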