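"""Cross-oracle validation harness binding all modules.

Every closed-form quantity in the package (spectra, eigenvectors, commute
times, mixing bounds) has an independent numeric oracle at desk scale:
brute-force eigendecomposition of the exact transition matrix, fundamental
matrix linear solves, and exact matrix powers for total variation.  The
harness runs those comparisons and reports machine-readable results with
the first counterexample on failure.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .host import HostGraph, build_host, fixture_host
from .edits import all_simple_edits, generate_semigroup, check_lrb
from .lattice import family_spectrum, simple_spectrum
from .chain import (
    EditFamily,
    mixing_bound,
    stationary_numeric,
    transition_matrix,
    tv_from_stationary,
)
from .eigensystem import (
    commute_time_full_sum,
    commute_time_spectral,
    hitting_times_solve,
    hitting_times_spectral,
    psi_family,
)
from .models import intersection_family, moran_family

__all__ = ["CheckResult", "ValidationReport", "run_validation", "SUITES"]


@dataclass
class CheckResult:
    name: str
    status: str  # "pass" | "fail"
    tolerance: float
    seed: int
    runtime: float
    witness: Optional[dict] = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class ValidationReport:
    suite: str
    max_m: int
    seed: int
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "suite": self.suite,
                "max_m": self.max_m,
                "seed": self.seed,
                "passed": self.passed,
                "checks": [asdict(c) for c in self.checks],
            },
            indent=2,
            default=str,
        )


def _timed(name, tol, seed, fn) -> CheckResult:
    t0 = time.perf_counter()
    witness = fn()
    dt = time.perf_counter() - t0
    status = "pass" if witness is None else "fail"
    return CheckResult(name, status, tol, seed, dt, witness)


def _path_host(m: int) -> HostGraph:
    return build_host([(i, i + 1) for i in range(1, m + 1)])


def _spectra_match(P: np.ndarray, expected: np.ndarray, tol: float):
    got = np.sort(np.linalg.eigvals(P).real)[::-1]
    expected = np.sort(np.asarray(expected))[::-1]
    if got.shape != expected.shape:
        return {"got_count": len(got), "expected_count": len(expected)}
    err = float(np.max(np.abs(got - expected)))
    if err > tol:
        return {"max_eigenvalue_error": err}
    return None


# ---------------------------------------------------------------------------
# Check suites
# ---------------------------------------------------------------------------


def check_lrb_suite(max_m: int, seed: int) -> list[CheckResult]:
    out = []

    def full_semigroup():
        for m in (2, 3):
            S = generate_semigroup(all_simple_edits(_path_host(m)))
            rep = check_lrb(S.elements, m=m, seed=seed)
            if not rep.passed:
                return rep.witness
        return None

    out.append(_timed("lrb/full-simple-semigroup", 0.0, seed, full_semigroup))

    def moran_lrb():
        family, _ = moran_family(fixture_host("k4"))
        S = generate_semigroup(list(family.edits))
        rep = check_lrb(S.elements, m=6, seed=seed, pair_cap=2000)
        return rep.witness

    out.append(_timed("lrb/moran-k4-closure", 0.0, seed, moran_lrb))
    return out


def check_spectrum_suite(max_m: int, seed: int) -> list[CheckResult]:
    rng = np.random.default_rng(seed)
    out = []

    def simple_vs_numeric():
        for host in (fixture_host("p3"), fixture_host("c5")):
            p = rng.uniform(0.1, 0.9, host.m)
            P = transition_matrix(EditFamily.simple_process(host, p)).P
            expected = simple_spectrum(host.m).eigenvalues_multiset()
            w = _spectra_match(P, expected, 1e-9)
            if w is not None:
                w["host_m"] = host.m
                return w
        return None

    out.append(_timed("spectrum/simple-vs-numeric", 1e-9, seed, simple_vs_numeric))

    def moran_vs_numeric():
        family, _ = moran_family(fixture_host("kn:3"))
        spec = family_spectrum(family)
        T = transition_matrix(family)
        # numeric spectrum restricted to the chamber block
        from .chain import recurrent_classes

        states = recurrent_classes(T)[0]
        P = T.P[np.ix_(states, states)]
        return _spectra_match(P, spec.eigenvalues_multiset(), 1e-9)

    out.append(_timed("spectrum/moran-k3-vs-numeric", 1e-9, seed, moran_vs_numeric))
    return out


def check_eigvec_suite(max_m: int, seed: int) -> list[CheckResult]:
    rng = np.random.default_rng(seed)
    out = []

    def phi_psi():
        host = fixture_host("p3")
        for p in (np.array([0.25, 0.25]), rng.uniform(0.1, 0.9, 2)):
            sys = psi_family(host, p)
            P = transition_matrix(EditFamily.simple_process(host, p)).P
            for T in range(4):
                lam = T.bit_count() / host.m
                err = float(np.max(np.abs(sys.phi[T] @ P - lam * sys.phi[T])))
                if err > 1e-10:
                    return {"T": T, "eigen_residual": err}
            gram = sys.psi @ sys.psi.T
            err = float(np.max(np.abs(gram - np.eye(4))))
            if err > 1e-10:
                return {"gram_error": err}
        return None

    out.append(_timed("eigvec/phi-psi-p3", 1e-10, seed, phi_psi))

    def diagonalization():
        host = fixture_host("p3")
        p = np.array([0.25, 0.25])
        sys = psi_family(host, p)
        P = transition_matrix(EditFamily.simple_process(host, p)).P
        U = sys.phi  # rows are left eigenvectors
        lam = np.array([T.bit_count() / host.m for T in range(4)])
        err = float(np.max(np.abs(U @ P - np.diag(lam) @ U)))
        if err > 1e-10:
            return {"diagonalization_residual": err}
        return None

    out.append(_timed("eigvec/diagonalization-p3", 1e-10, seed, diagonalization))
    return out


def check_commute_suite(max_m: int, seed: int) -> list[CheckResult]:
    rng = np.random.default_rng(seed)
    out = []

    def spectral_vs_solver():
        for name, p in (("p3", np.array([0.25, 0.25])), ("kn:3", None)):
            host = fixture_host(name)
            if p is None:
                p = rng.uniform(0.15, 0.85, host.m)
            sys = psi_family(host, p)
            P = transition_matrix(EditFamily.simple_process(host, p)).P
            hr = hitting_times_spectral(sys)
            H = hitting_times_solve(P)
            err = float(np.max(np.abs(hr.H - H)))
            if err > 1e-8:
                return {"host": name, "hitting_error": err}
            n = 1 << host.m
            for E in range(n):
                for F in range(n):
                    r = commute_time_spectral(E, F, sys)
                    f = commute_time_full_sum(E, F, sys)
                    if abs(r - f) > 1e-10 or abs(r - hr.C[E, F]) > 1e-8:
                        return {"host": name, "E": E, "F": F, "restricted": r, "full": f}
        return None

    out.append(_timed("commute/spectral-vs-solver", 1e-8, seed, spectral_vs_solver))
    return out


def check_mixing_suite(
    max_m: int,
    seed: int,
    lambda_star_override: Optional[float] = None,
) -> list[CheckResult]:
    """TV at the guaranteed times is at most e^{-c}.

    ``lambda_star_override`` substitutes a (possibly wrong) spectral gap in
    the compound bounds — a deliberately corrupted value falsifies the
    guarantee and produces a failing check with a witness.
    """
    out = []

    def simple_bounds():
        for m in range(2, min(max_m, 6) + 1):
            host = _path_host(m)
            rng = np.random.default_rng(seed + m)
            p = rng.uniform(0.1, 0.9, m)
            P = transition_matrix(EditFamily.simple_process(host, p)).P
            pi = stationary_simple_vec(host, p)
            for c in (1.0, 2.0, 3.0):
                t = mixing_bound("simple", m=m, c=c)
                tv = tv_from_stationary(P, pi, t)
                if float(tv.max()) > np.exp(-c):
                    return {"m": m, "c": c, "t": t, "tv_max": float(tv.max())}
        return None

    out.append(_timed("mixing/simple-guarantee", 0.0, seed, simple_bounds))

    def compound_bounds():
        from .chain import recurrent_classes

        cases = []
        fam_k4, _ = moran_family(fixture_host("k4"))
        cases.append(("moran-k4", fam_k4))
        fam_int, _ = intersection_family(3, 2, [1 / 3, 1 / 3, 1 / 3])
        cases.append(("intersection-3-2", fam_int))
        for name, family in cases:
            T = transition_matrix(family)
            states = recurrent_classes(T)[0]
            P = T.P[np.ix_(states, states)]
            spec = family_spectrum(family)
            lam_star = (
                lambda_star_override
                if lambda_star_override is not None
                else spec.lambda_star
            )
            pi = stationary_numeric(T)[states]
            m = family.host.m
            for c in (1.0, 2.0, 3.0):
                t = mixing_bound("compound", m=m, c=c, lambda_star=lam_star)
                tv = tv_from_stationary(P, pi, t)
                if float(tv.max()) > np.exp(-c):
                    return {
                        "family": name,
                        "c": c,
                        "t": t,
                        "lambda_star": lam_star,
                        "tv_max": float(tv.max()),
                    }
        return None

    out.append(_timed("mixing/compound-guarantee", 0.0, seed, compound_bounds))
    return out


def stationary_simple_vec(host, p):
    from .chain import stationary_simple

    return stationary_simple(host, p)


SUITES = {
    "lrb": check_lrb_suite,
    "spectrum": check_spectrum_suite,
    "eigvec": check_eigvec_suite,
    "commute": check_commute_suite,
    "mixing": check_mixing_suite,
}


def run_validation(suite: str = "all", max_m: int = 6, seed: int = 0) -> ValidationReport:
    """Run one named suite (or all); the report collects per-check status,
    tolerance, seed, runtime, and the first counterexample on failure."""
    if max_m > 10:
        raise ValueError("max_m must be <= 10")
    names = list(SUITES) if suite == "all" else [suite]
    for name in names:
        if name not in SUITES:
            raise ValueError(f"unknown suite: {name!r} (choose from {sorted(SUITES)})")
    report = ValidationReport(suite, max_m, seed)
    for name in names:
        report.checks.extend(SUITES[name](max_m, seed))
    return report
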