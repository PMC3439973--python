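"""Model / results facade over the full calling pipeline.

:class:`SVModel` holds the data (an alignment table) and the model
specification (library stats, Poisson rate, error probability, priors);
``fit()`` runs classification, clustering, likelihood scoring and the
mapping-matrix MCMC and returns an :class:`SVResults` carrying the final call
set, per-candidate scores, chain diagnostics and writers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .evaluation import PredictionRecord, evaluate_calls, roc_table
from .fragments import (ConcordantIndex, LibraryStats, MapabilityTrack,
                        Signature, Technology, classify_table,
                        estimate_length_bounds, filter_alignment_table,
                        partition_table)
from .geometry import cluster_discordants
from .likelihood import ModelParams, column_model
from .mcmc import build_alignment_matrix, build_components, run_chain, \
    unique_only_summary
from .reporting import calls_to_frame, finalize
from .simulate import SimResult

__all__ = ["SVModel", "SVResults"]


class SVModel:
    """Probabilistic structural-variant caller over paired-end alignments.

    Parameters
    ----------
    alignments
        One row per candidate fragment placement (columns
        ``fragment_id, chrom1, pos1, strand1, len1, chrom2, pos2, strand2,
        len2, mapq``).
    stats
        Library fragment-length bounds; estimated from the concordant span
        distribution when omitted.
    lam
        Fragment rate per base. When omitted it is estimated as the number of
        concordant fragments divided by the indexed genome length.
    mapability
        Optional per-base uniqueness track used to scale concordant counts
        over candidate deletion intervals.
    """

    def __init__(self, alignments: pd.DataFrame,
                 stats: LibraryStats | None = None,
                 lam: float | None = None,
                 p_err: float = 0.01,
                 eta: float = 1e-3,
                 alpha_map: float = 0.3,
                 beta_map: float = 0.7,
                 cap_quantile: float = 0.9999,
                 mapability: MapabilityTrack | None = None,
                 chrom_lengths: dict[str, int] | None = None,
                 technology: Technology = Technology.ILLUMINA,
                 min_mapq: int = 10,
                 max_span: int = 500_000,
                 max_alignments: int = 100):
        self.alignments = alignments
        self.stats = stats
        self.lam = lam
        self.p_err = p_err
        self.eta = eta
        self.alpha_map = alpha_map
        self.beta_map = beta_map
        self.cap_quantile = cap_quantile
        self.mapability = mapability or MapabilityTrack.uniform()
        self.chrom_lengths = chrom_lengths
        self.technology = technology
        self.min_mapq = min_mapq
        self.max_span = max_span
        self.max_alignments = max_alignments

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_sam(cls, path, **kwargs) -> "SVModel":
        return cls(_io.read_sam(path), **kwargs)

    @classmethod
    def from_table(cls, path, **kwargs) -> "SVModel":
        return cls(_io.read_alignment_table(path), **kwargs)

    @classmethod
    def from_simulation(cls, sim: SimResult, use_true_stats: bool = False,
                        **kwargs) -> "SVModel":
        kwargs.setdefault("mapability", sim.mapability)
        kwargs.setdefault("chrom_lengths",
                          {sim.config.chrom: sim.config.ref_length})
        kwargs.setdefault("p_err", sim.config.p_err)
        kwargs.setdefault("technology", sim.config.technology)
        if use_true_stats:
            kwargs.setdefault("stats", sim.library_stats)
        return cls(sim.alignments, **kwargs)

    # -- fitting --------------------------------------------------------------

    def _estimate_stats(self, df: pd.DataFrame):
        """Library stats from the concordant span distribution; estimated per
        read group when the table carries a ``library`` column."""
        if "library" in df.columns:
            return {str(lib): self._estimate_stats(
                sub.drop(columns="library"))
                for lib, sub in df.groupby("library")}
        same = (df["chrom1"] == df["chrom2"]).to_numpy()
        unique = ~df["fragment_id"].duplicated(keep=False).to_numpy()
        p1 = df["pos1"].to_numpy(np.int64)
        p2 = df["pos2"].to_numpy(np.int64)
        s1 = df["strand1"].to_numpy(bool)
        s2 = df["strand2"].to_numpy(bool)
        l1 = df["len1"].to_numpy(np.int64)
        l2 = df["len2"].to_numpy(np.int64)
        left_first = p1 <= p2
        lstr = np.where(left_first, s1, s2)
        rstr = np.where(left_first, s2, s1)
        convergent = lstr & ~rstr  # Illumina convention
        span = np.where(left_first, p2 + l2 - 1 - p1, p1 + l1 - 1 - p2) + 1
        spans = span[same & unique & convergent & (span > 0)]
        if spans.size:
            # robust trim: convergent pairs straddling deletions inflate the
            # upper tail, so restrict to a wide MAD band before the quantile
            # rule (10 * MAD ~ 6.7 sigma for a normal fragment-length law)
            med = np.median(spans)
            mad = np.median(np.abs(spans - med))
            if mad > 0:
                spans = spans[np.abs(spans - med) <= 10 * mad]
        readlength = int(np.median(np.concatenate([l1, l2])))
        return estimate_length_bounds(spans, readlength,
                                      technology=self.technology)

    def fit(self, seed: int = 0, burn_in: int = 100_000,
            n_samples: int = 900_000, tau: float = 0.5,
            threshold: float = 0.0, min_support: int = 1,
            hq_only: bool = False, use_mcmc: bool = True,
            sample_unique: bool = False, breakend_only: bool = False,
            homozygous_only: bool = False, deletion_span_gate: bool = False,
            max_component_edges: int = 10 ** 6,
            prune_calls: bool = True) -> "SVResults":
        """Run the full pipeline and return the fitted results.

        ``hq_only`` restricts the discordant set to uniquely mapped fragments
        (the high-quality mode); ``use_mcmc=False`` skips the sampler and
        scores candidates directly from the unique assignments (identical to
        the MCMC path when every fragment is unique). ``min_support=2``
        reproduces the stricter two-fragment reporting variant.
        """
        stats_in = self.stats or self._estimate_stats(self.alignments)
        if isinstance(stats_in, dict):
            # mixed libraries: per-library bounds for classification and
            # geometry; a single pooled summary feeds the (global-rate) model
            members = list(stats_in.values())
            counts = self.alignments["library"].value_counts()
            weights = np.array([counts.get(k, 0) for k in stats_in])
            lavg = float(np.average([s.lavg for s in members],
                                    weights=weights))
            stats = LibraryStats(
                lmin=min(s.lmin for s in members),
                lmax=max(s.lmax for s in members), lavg=lavg,
                readlength=int(np.median([s.readlength for s in members])),
                technology=members[0].technology)
        else:
            stats = stats_in
        df = classify_table(self.alignments, stats_in)
        df, filter_stats = filter_alignment_table(
            df, self.min_mapq, self.max_span, self.max_alignments)
        concordant, discordant, excluded = partition_table(df)

        chrom_lengths = self.chrom_lengths
        if chrom_lengths is None:
            ends = df.groupby("chrom1", observed=True)["end"].max()
            chrom_lengths = {str(c): int(v) for c, v in ends.items()}
        coverage = ConcordantIndex.from_table(concordant, chrom_lengths)

        lam = self.lam
        if lam is None:
            n_conc = concordant["fragment_id"].nunique()
            genome = sum(chrom_lengths.values())
            lam = n_conc / genome
        params = ModelParams(
            lam=lam, lavg=stats.lavg, readlength=stats.readlength,
            p_err=self.p_err, eta=self.eta, alpha_map=self.alpha_map,
            beta_map=self.beta_map, cap_quantile=self.cap_quantile)

        disc = discordant
        if hq_only:
            counts = disc.groupby("fragment_id")["x"].transform("size")
            disc = disc[counts == 1]
        if deletion_span_gate:
            gate = ((disc["sig"] != int(Signature.DELETION))
                    | (disc["span"] >= 2 * stats.lmax))
            disc = disc[gate]

        candidates = cluster_discordants(disc, stats)
        column_models = {
            c.id: column_model(c, coverage, self.mapability, params,
                               breakend_only=breakend_only,
                               homozygous_only=homozygous_only)
            for c in candidates
        }
        matrix = build_alignment_matrix(candidates)
        components, fixed_assign = build_components(
            matrix, column_models, params,
            fix_unique=not sample_unique)

        chains = []
        if use_mcmc:
            ss = np.random.SeedSequence(seed)
            child_seeds = ss.generate_state(max(len(components), 1)) % (2 ** 31)
            for comp, cseed in zip(components, child_seeds):
                if comp.matrix.n_edges > max_component_edges:
                    warnings.warn(
                        f"component with {comp.matrix.n_edges} edges exceeds "
                        "the sampling ceiling; assigning unique rows only")
                    chains.append(unique_only_summary(comp))
                else:
                    chains.append(run_chain(comp, burn_in=burn_in,
                                            n_samples=n_samples,
                                            seed=int(cseed)))
        else:
            # direct path: unique rows keep their fixed assignment, ambiguous
            # rows stay unassigned
            chains = [unique_only_summary(comp) for comp in components]

        calls = finalize(chains, candidates, column_models, fixed_assign,
                         tau=tau, threshold=threshold,
                         min_support=min_support, do_prune=prune_calls)
        return SVResults(
            model=self, params=params, stats=stats, candidates=candidates,
            column_models=column_models, matrix=matrix, components=components,
            chains=chains, fixed_assignments=fixed_assign, calls=calls,
            coverage=coverage,
            diagnostics={
                "n_fragments": int(df["fragment_id"].nunique()),
                "n_concordant": int(concordant["fragment_id"].nunique()),
                "n_discordant": int(discordant["fragment_id"].nunique()),
                "n_excluded": int(excluded["fragment_id"].nunique()),
                "n_candidates": len(candidates),
                "n_components_sampled": len(components),
                "filter": filter_stats,
                "lam": lam,
            },
            chrom_lengths=chrom_lengths,
            fit_options={
                "seed": seed, "burn_in": burn_in, "n_samples": n_samples,
                "tau": tau, "threshold": threshold,
                "min_support": min_support, "hq_only": hq_only,
                "use_mcmc": use_mcmc, "sample_unique": sample_unique,
                "breakend_only": breakend_only,
                "homozygous_only": homozygous_only,
            },
        )


@dataclass
class SVResults:
    """Fitted call set with scores, uncertainties and diagnostics."""

    model: SVModel
    params: ModelParams
    stats: LibraryStats
    candidates: list
    column_models: dict
    matrix: object
    components: list
    chains: list
    fixed_assignments: dict
    calls: list
    coverage: ConcordantIndex
    diagnostics: dict
    chrom_lengths: dict
    fit_options: dict = field(default_factory=dict)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    # -- evaluation ----------------------------------------------------------

    def prediction_records(self, eps: float | None = None
                           ) -> list[PredictionRecord]:
        if eps is None:
            eps = self.stats.lmax / 2
        return [
            PredictionRecord(chrom=c.chrom, x=c.start, y=c.end, eps=eps,
                             score=c.log_lambda, svtype=c.svtype,
                             copy_call=c.copy_call)
            for c in self.calls
        ]

    def evaluate(self, truth, eps: float | None = None) -> dict:
        """Match calls against a known-variant set with the double-uncertainty
        metric (default prediction uncertainty Lmax/2)."""
        return evaluate_calls(self.prediction_records(eps), truth)

    def roc(self, truth, eps: float | None = None) -> pd.DataFrame:
        return roc_table(self.prediction_records(eps), truth)

    def plot_roc(self, truth, eps: float | None = None, ax=None):
        import matplotlib.pyplot as plt

        tab = self.roc(truth, eps)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(tab["novel"], tab["tp"], marker="o")
        ax.set_xlabel("novel predictions")
        ax.set_ylabel("true positives")
        return ax

    # -- output --------------------------------------------------------------

    def to_bedpe(self, path) -> None:
        _io.write_calls_bedpe(self.calls, path)

    def to_vcf(self, path) -> None:
        echo = (f"lam={self.params.lam:.6g},p_err={self.params.p_err},"
                f"eta={self.params.eta},lavg={self.params.lavg:.6g},"
                f"lmin={self.stats.lmin},lmax={self.stats.lmax}")
        _io.write_vcf(self.calls, path, self.chrom_lengths, params_echo=echo)

    def summary(self) -> str:
        d = self.diagnostics
        by_type: dict[str, int] = {}
        for c in self.calls:
            by_type[c.svtype] = by_type.get(c.svtype, 0) + 1
        lines = [
            "Structural-variant call summary",
            "=" * 46,
            f"fragments            {d['n_fragments']:>12}",
            f"  concordant         {d['n_concordant']:>12}",
            f"  discordant         {d['n_discordant']:>12}",
            f"  excluded (mixed)   {d['n_excluded']:>12}",
            f"candidate variants   {d['n_candidates']:>12}",
            f"sampled components   {d['n_components_sampled']:>12}",
            f"final calls          {len(self.calls):>12}",
        ]
        for t, n in sorted(by_type.items()):
            lines.append(f"  {t:<18} {n:>12}")
        lines += [
            "-" * 46,
            f"lambda (frag/base)   {self.params.lam:>12.4f}",
            f"lambda_c             {self.params.lam_c:>12.2f}",
            f"lambda_d             {self.params.lam_d:>12.2f}",
            f"p_err                {self.params.p_err:>12.3g}",
            f"[Lmin, Lmax]         [{self.stats.lmin}, {self.stats.lmax}]",
        ]
        if self.calls:
            lines += ["-" * 46,
                      "top calls (by log-likelihood ratio):"]
            for c in self.calls[:10]:
                lines.append(
                    f"  {c.svtype} {c.chrom}:{c.start}-{c.end} k={c.support} "
                    f"c={c.copy_call} logLR={c.log_lambda:.1f}")
        return "\n".join(lines)
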