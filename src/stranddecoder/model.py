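"""Model/Results facades over the decoder toolkit.

``GeneticDecoder`` wraps a genotype–phenotype table plus a class-interval
spec the way a statistical model wraps data: ``fit()`` learns the allele
coefficient array and returns a :class:`DecoderFit` carrying the weights,
the separability diagnostics and a ``summary()`` table.  Circuit
compilation, kinetic simulation, cohort decoding and plotting hang off the
fit.  ``PRSModel`` does the same for polygenic scoring models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import fixtures
from .compiler import (
    Circuit,
    DEFAULT_BASE_UNIT_NM,
    PRS_BASE_UNIT_NM,
    PRS_MULTIPLIER_NM,
    compile_circuit,
    compile_prs,
)
from .crn import (
    Trajectory,
    build_reaction_network,
    default_calibration,
    endpoint_rfu,
    simulate,
)
from .decode import (
    DecodeTable,
    PipelineConfig,
    calls_to_frame,
    decode_table_from_rules,
    run_pipeline,
)
from .errors import InputError
from .genotype import GenotypePhenotypeTable
from .learn import (
    ClassIntervalSpec,
    CoefficientArray,
    SeparabilityReport,
    SolverConfig,
    learn_coefficients,
    verify_separability,
)
from .prs import (
    PrsResult,
    ScoringModel,
    circuit_net_score,
    compute_prs,
    sample_population,
    stratify,
)

_FIXTURES = {
    "CYP2C19": (
        fixtures.cyp2c19_table,
        fixtures.cyp2c19_interval_spec,
        fixtures.cyp2c19_decode_rules,
        ("VIC", "Cy5", "FAM", "ROX"),
    ),
    "DPYD": (
        fixtures.dpyd_table,
        fixtures.dpyd_interval_spec,
        fixtures.dpyd_decode_rules,
        ("VIC", "Cy5", "ROX"),
    ),
    "TPMT": (
        fixtures.tpmt_table,
        fixtures.thiopurine_interval_spec,
        None,
        None,
    ),
    "NUDT15": (
        fixtures.nudt15_table,
        fixtures.thiopurine_interval_spec,
        None,
        None,
    ),
}


class GeneticDecoder:
    """Linear genotype-to-phenotype separability model for one gene panel."""

    def __init__(
        self,
        table: GenotypePhenotypeTable,
        interval_spec: ClassIntervalSpec,
        decode_table: DecodeTable | None = None,
    ):
        self.table = table
        self.interval_spec = interval_spec
        self.decode_table = decode_table

    @classmethod
    def from_fixture(cls, name: str) -> "GeneticDecoder":
        try:
            table_fn, spec_fn, rules_fn, channels = _FIXTURES[name]
        except KeyError:
            raise InputError(
                f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
            )
        decode_table = (
            decode_table_from_rules(rules_fn(), channels) if rules_fn else None
        )
        return cls(table_fn(), spec_fn(), decode_table)

    @property
    def panel(self):
        return self.table.panel

    def fit(
        self,
        margin: float | None = None,
        weight_bound: float = 8.0,
        integer_only: bool = False,
    ) -> "DecoderFit":
        cfg = SolverConfig(
            margin=margin, weight_bound=weight_bound, integer_only=integer_only
        )
        weights = learn_coefficients(self.table, self.interval_spec, cfg)
        report = verify_separability(self.table, weights, self.interval_spec)
        return DecoderFit(model=self, weights=weights, separability=report)


@dataclass
class DecoderFit:
    """Learned coefficient array plus diagnostics and downstream stages."""

    model: GeneticDecoder
    weights: CoefficientArray
    separability: SeparabilityReport
    _circuit: Circuit | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            self.weights.weights, index=list(self.weights.allele_labels),
            name="weight",
        )

    def compile(self, base_unit: float = DEFAULT_BASE_UNIT_NM) -> Circuit:
        if self._circuit is None or self._circuit.base_unit != base_unit:
            self._circuit = compile_circuit(
                self.weights, self.model.interval_spec, base_unit
            )
        return self._circuit

    def decode(
        self,
        samples: Sequence[tuple[str, object]] | None = None,
        config: PipelineConfig | None = None,
    ) -> pd.DataFrame:
        """Run the full molecular pipeline over a cohort (default: every
        genotype of the model's table) and return the call report."""
        if self.model.decode_table is None:
            raise InputError("no decode table attached to this model")
        if samples is None:
            samples = [
                (str(dip) if dip else f"g{i}", dip if dip else code)
                for i, (dip, code, _) in enumerate(self.model.table.entries)
            ]
        calls = run_pipeline(
            samples,
            self.model.panel,
            self.weights,
            self.model.interval_spec,
            self.model.decode_table,
            config,
            circuit=self.compile(
                config.base_unit if config else DEFAULT_BASE_UNIT_NM
            ),
        )
        return calls_to_frame(calls)

    def simulate_genotype(
        self, diplotype: str, config: PipelineConfig | None = None
    ) -> tuple[Trajectory, dict]:
        """Kinetic trajectory and endpoint RFU for a single genotype."""
        from .genotype import Diplotype, encode_genetic_code
        from .ldr import default_primer_panel, transform

        cfg = config or PipelineConfig()
        circuit = self.compile(cfg.base_unit)
        panel = self.model.panel
        code = encode_genetic_code(Diplotype.parse(panel.gene, diplotype), panel)
        inputs = transform(
            code, default_primer_panel(panel), cfg.ldr, "endpoint",
            panel.allele_labels(),
        )
        wired = {a: c for a, c in inputs.items() if a in circuit.input_map}
        network = build_reaction_network(circuit, wired, cfg.rates)
        traj = simulate(network, cfg.t_end, cfg.reltol, cfg.abstol)
        rfu = endpoint_rfu(traj, default_calibration(circuit))
        return traj, rfu

    def plot_trajectory(self, trajectory: Trajectory, species=None, ax=None):
        """Plot species trajectories (fluorophores by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = species or [
            s for s in trajectory.species if s.startswith("FLUOR:")
        ]
        for name in names:
            ax.plot(trajectory.times / 60.0, trajectory.series(name), label=name)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (nM)")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        rep = self.separability
        lines = [
            "Genetic decoder fit",
            "=" * 55,
            f"panel:            {self.weights.panel_id}",
            f"genotypes:        {self.model.table.n_genotypes}",
            f"classes:          {', '.join(self.model.interval_spec.classes)}",
            f"boundaries (1x):  {list(self.model.interval_spec.boundaries)}",
            f"feasible:         {rep.feasible}",
            f"achieved margin:  {rep.achieved_margin:.3f}",
            "-" * 55,
            f"{'allele':>14} {'weight (1x)':>12}",
        ]
        for lab, w in self.params.items():
            lines.append(f"{lab:>14} {w:>12.3f}")
        lines.append("-" * 55)
        lines.append(f"{'class':>14} {'score range':>20}")
        for lab, (lo, hi) in rep.class_ranges.items():
            lines.append(f"{lab:>14} {f'[{lo:.2f}, {hi:.2f}]':>20}")
        return "\n".join(lines)


class PRSModel:
    """Polygenic-score model with molecular-encoding diagnostics."""

    def __init__(self, scoring_model: ScoringModel):
        self.scoring_model = scoring_model

    @classmethod
    def from_file(cls, path) -> "PRSModel":
        from .prs import parse_scoring_file

        return cls(parse_scoring_file(path))

    @classmethod
    def from_synthetic(cls, n_variants: int = 22, seed: int = 20230101):
        return cls(fixtures.synthetic_scoring_model(n_variants, seed))

    def simulate_cohort(self, n: int, seed: int = 0):
        return sample_population(self.scoring_model, n, seed)

    def fit(self, cohort=None, n: int = 2504, seed: int = 0) -> "PRSFit":
        """Score a cohort (simulated under Hardy–Weinberg by default)."""
        if cohort is None:
            cohort = self.simulate_cohort(n, seed)
        result = stratify(compute_prs(cohort, self.scoring_model))
        return PRSFit(model=self, cohort=cohort, result=result)

    def compile(
        self,
        encoding: str = "paper_literal",
        base_unit: float = PRS_BASE_UNIT_NM,
        multiplier: float = PRS_MULTIPLIER_NM,
        screen_threshold: float | None = None,
    ) -> Circuit:
        return compile_prs(
            self.scoring_model, encoding, base_unit, multiplier,
            screen_threshold,
        )


@dataclass
class PRSFit:
    model: PRSModel
    cohort: object
    result: PrsResult

    def to_frame(self) -> pd.DataFrame:
        df = self.result.to_frame()
        sm = self.model.scoring_model
        df["circuit_net_literal"] = [
            circuit_net_score(row, sm, "paper_literal")
            for row in self.cohort.dosages
        ]
        df["literal_offset"] = df["prs"] - df["circuit_net_literal"]
        return df

    @property
    def top_decile_threshold(self) -> float:
        return float(self.result.decile_boundaries[-1])

    def summary(self) -> str:
        r = self.result
        counts = {
            c: r.categories.count(c) for c in ("low", "intermediate", "high")
        }
        df = self.to_frame()
        lines = [
            "Polygenic risk score fit",
            "=" * 55,
            f"scoring model:      {self.model.scoring_model.pgs_id} "
            f"({self.model.scoring_model.n_variants} variants)",
            f"cohort size:        {len(r.scores)}",
            f"mean (lnOR units):  {r.mean:.3f}",
            f"sd:                 {r.sd:.3f}",
            f"top decile cut:     {self.top_decile_threshold:.3f}",
            f"categories:         low={counts['low']}, "
            f"intermediate={counts['intermediate']}, high={counts['high']}",
            f"literal-encoding offset (mean): "
            f"{df['literal_offset'].mean():.3f}",
        ]
        return "\n".join(lines)
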