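"""Real-coded genetic algorithm for intraocular-lens design.

The design vector holds the six IOL genes — anterior curvature c4 and conic
K4, anterior thickness t4, mid thickness t5, posterior curvature c6 and
conic K6 — injected into surfaces #4/#5/#6 of a base prescription.  Each
candidate is scored by the weighted aberration merit

    fin = w1 |SA| + w2 |TCO|

evaluated from the Seidel sums at the configured field angle (smaller is
better).  Selection is roulette-wheel on the reflected fitness
``fit_roulette(i) = (fit_max + fit_min) - fin(i)`` so lower merit gets a
proportionally larger wheel slice; crossover is the convex blend
``z = beta x + (1 - beta) y``; mutation steps a gene by ``+- beta Delta``
and clamps to bounds.  An optional damped-least-squares (Levenberg-style)
polish refines the generation best.

Reproducibility: one seeded generator drives every draw, in documented
order per generation — selection alphas (two per pairing), crossover gate,
blend beta, then per offspring the mutation trigger alpha and, if
triggered, per-gene beta and sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .eye_model import (
    STUDY_ERROR,
    EyePrescription,
    apply_refractive_error,
    builtin_prescription,
)
from .metrics import seidel_aberrations
from .trace_engine import TraceError, paraxial_trace

__all__ = [
    "GENE_NAMES",
    "DEFAULT_BOUNDS",
    "DesignVector",
    "Individual",
    "GAConfig",
    "RouletteTable",
    "GAResult",
    "InfeasiblePopulation",
    "NEUTRAL_GENES",
    "myopic_iol_base",
    "fitness",
    "build_roulette",
    "select",
    "crossover",
    "mutate",
    "make_evaluator",
    "inject_genes",
    "extract_genes",
    "dls_polish",
    "levenberg_refine",
    "run_ga",
]

GENE_NAMES = (
    "anterior_curvature",   # c4, mm^-1
    "anterior_conic",       # K4
    "anterior_thickness",   # t4, mm
    "mid_thickness",        # t5, mm
    "posterior_curvature",  # c6, mm^-1
    "posterior_conic",      # K6
)

# Bounds bracket all transcribed designs: curvature +-0.2 mm^-1,
# conic [-30, 5], thickness [0.05, 2.5] mm.
DEFAULT_BOUNDS = (
    np.array([-0.2, -30.0, 0.05, 0.05, -0.2, -30.0]),
    np.array([0.2, 5.0, 2.5, 2.5, 0.2, 5.0]),
)

# Surface positions of the IOL within a prescription's surface list
# (0-based: cornea 0, aqueous 1, stop 2, IOL 3-5, retina 6).
_IOL_ANTERIOR, _IOL_MID, _IOL_POSTERIOR = 3, 4, 5


class InfeasiblePopulation(RuntimeError):
    """No individual in the population could be evaluated."""


#: A deliberately uncorrecting IOL (flat surfaces, 1 mm gaps): the
#: "unoptimized start" against which GA improvement is measured.
NEUTRAL_GENES = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0])


def myopic_iol_base(pupil_diameter: float = 6.0, error_mode: str = "axial",
                    genes: np.ndarray | None = None) -> EyePrescription:
    """The myopic/astigmatic study eye fitted with an IOL to be optimized.

    Takes the IOL scaffold (anterior segment, acrylic IOL surfaces with the
    design-table semi-apertures, retina) at the requested pupil, applies the
    550-degree-myopia / 175-degree-astigmatism condition under
    ``error_mode``, and installs ``genes`` (default :data:`NEUTRAL_GENES`)
    as the starting IOL.
    """
    scaffold = "codev_5mm" if pupil_diameter <= 5.0 else "codev_6mm"
    base = builtin_prescription(scaffold, pupil_diameter)
    base = apply_refractive_error(base, STUDY_ERROR, mode=error_mode)
    out = inject_genes(base, NEUTRAL_GENES if genes is None else genes)
    return replace(out, name=f"myopic_iol_{pupil_diameter:g}mm")


@dataclass(frozen=True)
class DesignVector:
    """Six IOL genes with per-gene bounds."""

    genes: np.ndarray
    lower: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS[0].copy())
    upper: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS[1].copy())

    def __post_init__(self):
        g = np.asarray(self.genes, dtype=float)
        if g.shape != (len(GENE_NAMES),):
            raise ValueError(f"expected {len(GENE_NAMES)} genes, got shape {g.shape}")
        object.__setattr__(self, "genes", g)

    def clipped(self) -> "DesignVector":
        return replace(self, genes=np.clip(self.genes, self.lower, self.upper))

    def in_bounds(self, atol: float = 0.0) -> bool:
        return bool(np.all(self.genes >= self.lower - atol)
                    and np.all(self.genes <= self.upper + atol))


@dataclass
class Individual:
    """A candidate design with its evaluated aberrations and merit."""

    genes: np.ndarray
    sa: float
    tco: float
    fin: float


@dataclass
class GAConfig:
    """Hyperparameters of the genetic optimizer.

    Defaults follow the published run: population 100, 70 generations,
    crossover rate 0.8, mutation rate 0.2, unit weights.  ``delta`` is the
    per-gene mutation step bound (defaults to 5% of each gene's range).
    ``mutation_condition``: 'as_published' triggers mutation when the drawn
    alpha exceeds p_m (an unusual, high-trigger reading of the source
    condition); 'standard' triggers when alpha < p_m.  ``elitism`` > 0
    carries the best individuals forward unchanged, making the best merit
    non-increasing.
    """

    pop_size: int = 100
    generations: int = 70
    crossover_rate: float = 0.8
    p_m: float = 0.2
    w1: float = 1.0
    w2: float = 1.0
    delta: np.ndarray | None = None
    seed: int = 0
    mutation_condition: str = "as_published"
    elitism: int = 1
    dls_polish: bool = False
    field_deg: float = 5.0
    gene_mask: np.ndarray | None = None  # genes the GA may vary (default: all)

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for r, nm in ((self.crossover_rate, "crossover_rate"), (self.p_m, "p_m")):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")
        if self.mutation_condition not in ("as_published", "standard"):
            raise ValueError("mutation_condition must be 'as_published' or 'standard'")

    def resolved_delta(self, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            return np.full(len(GENE_NAMES), float(d)) if d.ndim == 0 else d
        return 0.05 * (upper - lower)

    def resolved_mask(self) -> np.ndarray:
        if self.gene_mask is None:
            return np.ones(len(GENE_NAMES), dtype=bool)
        return np.asarray(self.gene_mask, dtype=bool)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def fitness(sa: float, tco: float, w1: float = 1.0, w2: float = 1.0) -> float:
    """Weighted aberration merit fin = w1 |SA| + w2 |TCO| (single field)."""
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be >= 0")
    return w1 * abs(sa) + w2 * abs(tco)


@dataclass
class RouletteTable:
    """Selection wheel built from reflected fitness (minimisation)."""

    fit_roulette: np.ndarray
    q: np.ndarray  # selection probabilities, sum 1
    v: np.ndarray  # cumulative probabilities, v[-1] = 1


def build_roulette(fits: Sequence[float]) -> RouletteTable:
    """Wheel slices from ``fit_roulette(i) = (fit_max + fit_min) - fin(i)``.

    Lower merit gets a larger slice.  A degenerate population (all merits
    identical, including all zero) receives a uniform wheel.
    """
    f = np.asarray(fits, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 individuals")
    finite = np.isfinite(f)
    if not finite.any():
        raise InfeasiblePopulation("no finite fitness in population")
    fmax = f[finite].max()
    fmin = f[finite].min()
    fr = np.where(finite, (fmax + fmin) - f, 0.0)
    total = fr.sum()
    if total <= 0.0 or not math.isfinite(total):
        q = np.where(finite, 1.0, 0.0)
        q = q / q.sum()
    else:
        q = fr / total
    v = np.cumsum(q)
    v[-1] = 1.0
    return RouletteTable(fit_roulette=fr, q=q, v=v)


def select(table: RouletteTable, alpha: float) -> int:
    """Index i with v(i-1) < alpha <= v(i), v(0) = 0 (0-based)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return int(np.searchsorted(table.v, alpha, side="left"))


def crossover(x: DesignVector, y: DesignVector, beta: float) -> DesignVector:
    """Convex blend z = beta x + (1 - beta) y; stays in bounds automatically."""
    if not (np.array_equal(x.lower, y.lower) and np.array_equal(x.upper, y.upper)):
        raise ValueError("parents must share gene bounds")
    return replace(x, genes=beta * x.genes + (1.0 - beta) * y.genes)


def mutate(z: DesignVector, beta, sign, config: GAConfig) -> DesignVector:
    """Per-gene step ``z_i +- beta_i Delta_i`` on masked genes, clamped."""
    delta = config.resolved_delta(z.lower, z.upper)
    mask = config.resolved_mask()
    beta = np.broadcast_to(np.asarray(beta, dtype=float), z.genes.shape)
    sign = np.broadcast_to(np.asarray(sign, dtype=float), z.genes.shape)
    step = np.where(mask, sign * beta * delta, 0.0)
    return replace(z, genes=np.clip(z.genes + step, z.lower, z.upper))


# ---------------------------------------------------------------------------
# Evaluation against a prescription
# ---------------------------------------------------------------------------

def inject_genes(base: EyePrescription, genes: np.ndarray) -> EyePrescription:
    """Return the base prescription with IOL genes written into #4/#5/#6."""
    c4, k4, t4, t5, c6, k6 = (float(g) for g in genes)
    out = base.replace_surface(_IOL_ANTERIOR, curvature=c4, conic=k4, thickness=t4)
    out = out.replace_surface(_IOL_MID, thickness=t5)
    out = out.replace_surface(_IOL_POSTERIOR, curvature=c6, conic=k6)
    return out


def extract_genes(p: EyePrescription) -> np.ndarray:
    """Read the six IOL genes out of a prescription."""
    a, m, b = p.surfaces[_IOL_ANTERIOR], p.surfaces[_IOL_MID], p.surfaces[_IOL_POSTERIOR]
    return np.array([a.curvature, a.conic, a.thickness, m.thickness, b.curvature, b.conic])


def make_evaluator(base: EyePrescription, config: GAConfig) -> Callable[[np.ndarray], Individual]:
    """Closure mapping genes -> evaluated :class:`Individual`.

    A candidate whose paraxial solution is degenerate (afocal or otherwise
    untraceable) gets infinite merit.
    """
    def evaluate(genes: np.ndarray) -> Individual:
        try:
            p = inject_genes(base, genes)
            summary = seidel_aberrations(p, paraxial_trace(p), field_deg=config.field_deg)
        except (TraceError, FloatingPointError):
            return Individual(genes=np.array(genes, dtype=float),
                              sa=math.nan, tco=math.nan, fin=math.inf)
        return Individual(
            genes=np.array(genes, dtype=float),
            sa=summary.sa, tco=summary.tco,
            fin=fitness(summary.sa, summary.tco, config.w1, config.w2),
        )

    return evaluate


# ---------------------------------------------------------------------------
# Damped-least-squares polish
# ---------------------------------------------------------------------------

def levenberg_refine(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    max_iter: int = 20,
    fd_rel: float = 1e-6,
    lam0: float = 1e-3,
) -> np.ndarray:
    """Bounded Levenberg (damped normal equations) descent on a residual.

    Finite-difference Jacobian; a step is accepted only when it lowers the
    sum of squared residuals, so the result never regresses.  Returns the
    best point found (possibly ``x0`` unchanged).
    """
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    r = residual_fn(x)
    cost = float(r @ r)
    lam = lam0
    h = fd_rel * (upper - lower)
    for _ in range(max_iter):
        J = np.empty((r.size, x.size))
        for j in range(x.size):
            xp = x.copy(); xp[j] = min(x[j] + h[j], upper[j])
            xm = x.copy(); xm[j] = max(x[j] - h[j], lower[j])
            dx = xp[j] - xm[j]
            if dx == 0.0:
                J[:, j] = 0.0
                continue
            J[:, j] = (residual_fn(xp) - residual_fn(xm)) / dx
        g = J.T @ r
        if np.linalg.norm(g) < 1e-14:
            break
        improved = False
        for _ in range(10):
            try:
                step = np.linalg.solve(J.T @ J + lam * np.eye(x.size), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            xn = np.clip(x + step, lower, upper)
            rn = residual_fn(xn)
            cn = float(rn @ rn)
            if math.isfinite(cn) and cn < cost:
                x, r, cost = xn, rn, cn
                lam = max(lam / 10.0, 1e-12)
                improved = True
                break
            lam *= 10.0
        if not improved:
            break
    return x


def dls_polish(genes: np.ndarray, base: EyePrescription, config: GAConfig | None = None,
               lower: np.ndarray | None = None, upper: np.ndarray | None = None) -> np.ndarray:
    """Local damped-least-squares refinement of one design.

    Residual vector (sqrt(w1) SA, sqrt(w2) TCO); guaranteed not to increase
    the merit ``fin``; on any numerical failure the input is returned.
    """
    config = config or GAConfig()
    lower = DEFAULT_BOUNDS[0] if lower is None else lower
    upper = DEFAULT_BOUNDS[1] if upper is None else upper
    evaluate = make_evaluator(base, config)
    sw1, sw2 = math.sqrt(config.w1), math.sqrt(config.w2)

    def residual(g):
        ind = evaluate(g)
        if not math.isfinite(ind.fin):
            return np.array([1e6, 1e6])
        return np.array([sw1 * ind.sa, sw2 * ind.tco])

    start = evaluate(genes)
    try:
        out = levenberg_refine(residual, genes, lower, upper)
    except Exception:
        return np.array(genes, dtype=float)
    if evaluate(out).fin <= start.fin:
        return out
    return np.array(genes, dtype=float)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

@dataclass
class GAResult:
    best: Individual
    history: list[dict]  # per generation: generation, best_fin, mean_fin, best_genes
    config: GAConfig


def run_ga(
    base: EyePrescription,
    config: GAConfig | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> GAResult:
    """Optimize the IOL genes of ``base`` with the real-coded GA.

    Initial population uniform within bounds (seeded); each generation
    evaluates, builds the roulette wheel, selects pairs, blends at the
    crossover rate, mutates under the configured trigger, optionally
    polishes the generation best with DLS, and carries elites forward.
    Returns the best-ever individual and the per-generation history.
    """
    config = config or GAConfig()
    lower, upper = bounds if bounds is not None else DEFAULT_BOUNDS
    mask = config.resolved_mask()
    rng = np.random.default_rng(config.seed)
    evaluate = make_evaluator(base, config)

    base_genes = extract_genes(base)
    pop = rng.uniform(lower, upper, size=(config.pop_size, len(GENE_NAMES)))
    pop[:, ~mask] = base_genes[~mask]  # frozen genes keep the base values

    history: list[dict] = []
    best_ever: Individual | None = None
    for gen in range(config.generations):
        individuals = [evaluate(g) for g in pop]
        fins = np.array([ind.fin for ind in individuals])
        if not np.isfinite(fins).any():
            raise InfeasiblePopulation(
                f"generation {gen}: no candidate evaluates to a finite merit"
            )
        order = np.argsort(fins)
        gen_best = individuals[order[0]]
        if config.dls_polish and math.isfinite(gen_best.fin):
            polished = dls_polish(gen_best.genes, base, config, lower, upper)
            cand = evaluate(polished)
            if cand.fin < gen_best.fin:
                gen_best = cand
                pop[order[0]] = cand.genes
                fins[order[0]] = cand.fin
        if best_ever is None or gen_best.fin < best_ever.fin:
            best_ever = gen_best
        history.append({
            "generation": gen,
            "best_fin": float(best_ever.fin),
            "mean_fin": float(fins[np.isfinite(fins)].mean()),
            "best_genes": gen_best.genes.copy(),
        })
        if gen == config.generations - 1:
            break
        table = build_roulette(fins)
        children = []
        elites = min(config.elitism, config.pop_size)
        for e in range(elites):
            children.append(pop[order[e]].copy())
        while len(children) < config.pop_size:
            a1, a2 = rng.uniform(0.0, 1.0, size=2)
            i = select(table, max(a1, 1e-300))
            j = select(table, max(a2, 1e-300))
            gate = rng.uniform()
            if gate < config.crossover_rate:
                beta = rng.uniform()
                c1 = beta * pop[i] + (1.0 - beta) * pop[j]
                c2 = beta * pop[j] + (1.0 - beta) * pop[i]
            else:
                c1, c2 = pop[i].copy(), pop[j].copy()
            for child in (c1, c2):
                if len(children) >= config.pop_size:
                    break
                trigger = rng.uniform()
                hit = (trigger > config.p_m if config.mutation_condition == "as_published"
                       else trigger < config.p_m)
                if hit:
                    beta_m = rng.uniform(size=len(GENE_NAMES))
                    sign = rng.choice((-1.0, 1.0), size=len(GENE_NAMES))
                    delta = config.resolved_delta(lower, upper)
                    child = child + np.where(mask, sign * beta_m * delta, 0.0)
                children.append(np.clip(child, lower, upper))
        pop = np.array(children)
    assert best_ever is not None
    return GAResult(best=best_ever, history=history, config=config)
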