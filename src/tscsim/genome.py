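"""Circular genome description, lattice discretization and topological domains.

The genome is a circle of ``length`` base pairs discretized into 60-nt lattice
sites.  Transcription units (TUs) and fixed proteic barriers live at bp
coordinates (0-based) and are mapped onto lattice sites.  Topological domains
are the arcs of the circle delimited by *cut points*: fixed barriers plus the
current positions of elongating RNA polymerases.  Torsional stress equilibrates
instantly within a domain, so each domain carries a single superhelical density
``sigma``.

Conventions: 0-based bp coordinates, half-open spans; lattice site of bp ``x``
is ``floor(x / unit_length)``.  With cut points ``c_0 < ... < c_{k-1}`` (lattice
sites), domain ``i`` covers the arc ``(c_i, c_{i+1}]`` going clockwise, of
length ``(c_{i+1} - c_i) mod n_sites``; the k domain lengths always sum to the
full lattice.  With no cut points the whole circle is one domain.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .response import PromoterResponse, TopoisomeraseModel

__all__ = [
    "TranscriptionUnit",
    "GenomeSpec",
    "DomainPartition",
    "discretize",
    "partition_domains",
]

DEFAULT_UNIT_LENGTH = 60  # nt per lattice site


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene with its promoter, transcribed span and supercoiling response.

    ``tss`` and ``terminator`` are bp coordinates; the strand determines the
    direction of elongation (terminator downstream of the TSS along the
    strand).  Inactive units are regulatory probes: their instantaneous
    initiation rate is recorded every step but they never recruit an RNAP.
    """

    id: str
    tss: int
    terminator: int
    strand: str
    k_on: float  # basal initiation rate, 1/s
    response: PromoterResponse = field(default_factory=PromoterResponse)
    active: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unit {self.id}: strand must be '+' or '-'")
        if self.k_on < 0:
            raise ValueError(f"unit {self.id}: k_on must be >= 0")

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1


@dataclass(frozen=True)
class GenomeSpec:
    """Circular genome with transcription units, barriers and topoisomerases."""

    length: int
    units: tuple[TranscriptionUnit, ...] = ()
    barriers: tuple[int, ...] = ()
    topoisomerases: tuple[TopoisomeraseModel, ...] = ()
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length < DEFAULT_UNIT_LENGTH:
            raise ValueError("genome length must be at least one lattice unit")
        if not self.circular:
            raise ValueError("only circular genomes are supported")
        if len(set(self.barriers)) != len(self.barriers):
            raise ValueError("barrier positions must be distinct")
        for b in self.barriers:
            if not 0 <= b < self.length:
                raise ValueError(f"barrier at {b} outside genome [0, {self.length})")
        seen: set[str] = set()
        for u in self.units:
            if u.id in seen:
                raise ValueError(f"duplicate transcription unit id {u.id!r}")
            seen.add(u.id)
            for pos in (u.tss, u.terminator):
                if not 0 <= pos < self.length:
                    raise ValueError(
                        f"unit {u.id}: coordinate {pos} outside genome"
                    )

    def validate_layout(self, unit_length: int = DEFAULT_UNIT_LENGTH) -> None:
        """Check the discretized layout: no overlaps, no TU spanning a barrier."""
        discretize(self, unit_length)


@dataclass
class DomainPartition:
    """Topological domains of the circle, delimited by cut points.

    ``cuts[i]`` is the lattice site of cut point i (sorted ascending);
    ``labels[i]`` names the element sitting at that cut (barrier or RNAP id);
    ``sigma[i]`` is the superhelical density of the domain *starting* at
    ``cuts[i]`` (the arc ``(cuts[i], cuts[i+1 mod k]]``).  With ``k == 0``,
    ``sigma`` holds the single whole-circle value.
    """

    n_sites: int
    cuts: list[int]
    labels: list[str]
    sigma: list[float]

    @classmethod
    def uniform(
        cls,
        n_sites: int,
        cut_sites: Sequence[int],
        labels: Sequence[str],
        sigma0: float,
    ) -> "DomainPartition":
        order = sorted(range(len(cut_sites)), key=lambda i: cut_sites[i])
        cuts = [cut_sites[i] for i in order]
        labs = [labels[i] for i in order]
        if len(set(cuts)) != len(cuts):
            raise ValueError("duplicate cut points")
        k = len(cuts)
        return cls(n_sites, cuts, labs, [sigma0] * max(k, 1))

    @property
    def n_domains(self) -> int:
        return max(len(self.cuts), 1)

    def domain_length(self, i: int) -> int:
        k = len(self.cuts)
        if k <= 1:
            return self.n_sites
        return (self.cuts[(i + 1) % k] - self.cuts[i]) % self.n_sites

    def lengths(self) -> list[int]:
        return [self.domain_length(i) for i in range(self.n_domains)]

    def domain_of_site(self, site: int) -> int:
        """Index of the domain containing ``site`` (cut sites belong to the
        domain that *ends* there)."""
        k = len(self.cuts)
        if k == 0:
            return 0
        # domain i is (cuts[i], cuts[i+1]]: find first cut >= site, its
        # domain index is (j - 1) mod k
        j = bisect_left(self.cuts, site)
        return (j - 1) % k

    def sigma_at_site(self, site: int) -> float:
        return self.sigma[self.domain_of_site(site)]

    def mean_sigma(self) -> float:
        """Length-weighted mean superhelical density (the conserved quantity
        in the absence of topoisomerases)."""
        if len(self.cuts) <= 1:
            return self.sigma[0]
        tot = 0.0
        for i in range(len(self.cuts)):
            tot += self.sigma[i] * self.domain_length(i)
        return tot / self.n_sites

    def weighted_content(self) -> float:
        """Total supercoil content sum_i sigma_i * L_i (lattice units)."""
        if len(self.cuts) <= 1:
            return self.sigma[0] * self.n_sites
        return sum(
            self.sigma[i] * self.domain_length(i) for i in range(len(self.cuts))
        )

    def check(self) -> None:
        if self.cuts != sorted(self.cuts):
            raise AssertionError("cut points not sorted")
        if len(set(self.cuts)) != len(self.cuts):
            raise AssertionError("duplicate cut points")
        if sum(self.lengths()) != self.n_sites:
            raise AssertionError("domain lengths do not sum to lattice size")
        for s in self.sigma:
            if not math.isfinite(s):
                raise AssertionError("non-finite sigma")

    # -- structural edits (supercoil-content conserving) -------------------

    def split(self, site: int, label: str) -> int:
        """Insert a cut at ``site``; both child domains inherit the parent
        sigma (conserves sum sigma*L).  Returns the new cut index."""
        if site in self.cuts:
            raise ValueError(f"cut point already present at site {site}")
        k = len(self.cuts)
        j = bisect_left(self.cuts, site)
        if k == 0:
            self.cuts.insert(0, site)
            self.labels.insert(0, label)
            # one cut -> still a single whole-circle domain
            return 0
        parent = (j - 1) % k
        self.cuts.insert(j, site)
        self.labels.insert(j, label)
        self.sigma.insert(j, self.sigma[parent] if j != 0 else self.sigma[-1])
        # when j == 0 the new first domain is carved out of the wrap-around
        # domain, which is the (previously) last one
        return j

    def merge_at(self, j: int) -> None:
        """Remove cut ``j``, merging its two flanking domains with the
        length-weighted sigma average (conserves sum sigma*L)."""
        k = len(self.cuts)
        if k == 0:
            raise ValueError("no cut to remove")
        if k == 1:
            del self.cuts[0]
            del self.labels[0]
            return  # sigma[0] already the whole-circle value
        left = (j - 1) % k
        la, lb = self.domain_length(left), self.domain_length(j)
        if self.sigma[left] == self.sigma[j]:  # exact split/merge round trip
            merged = self.sigma[left]
        else:
            merged = (self.sigma[left] * la + self.sigma[j] * lb) / (la + lb)
        del self.cuts[j]
        del self.labels[j]
        del self.sigma[j]
        self.sigma[left if left < j else left - 1] = merged

    def cut_index(self, label: str) -> int:
        return self.labels.index(label)

    def move_cut(self, j: int, direction: int) -> None:
        """Move cut ``j`` one site in ``direction`` (+1 clockwise), transferring
        one lattice unit of DNA -- and its supercoil content -- between the two
        flanking domains.  Densities are updated so sum sigma*L is conserved:
        the receiving domain absorbs one unit at the donating domain's density.
        """
        k = len(self.cuts)
        n = self.n_sites
        new = (self.cuts[j] + direction) % n
        if new in self.cuts:
            raise ValueError(f"site {new} already occupied by a cut")
        if k > 1:
            if direction > 0:
                # domain j (ahead) donates one unit to domain j-1 (behind)
                ahead, behind = j, (j - 1) % k
            else:
                ahead, behind = (j - 1) % k, j
            la = self.domain_length(ahead)
            lb = self.domain_length(behind)
            if la <= 1:
                raise ValueError("move would create a zero-length domain")
            self.sigma[behind] = (
                self.sigma[behind] * lb + self.sigma[ahead]
            ) / (lb + 1)
        # reposition, preserving sort order (wrap rotates the lists)
        if direction > 0 and self.cuts[j] == n - 1:
            assert j == k - 1
            self.cuts.pop()
            lab = self.labels.pop()
            sig = self.sigma.pop()
            self.cuts.insert(0, 0)
            self.labels.insert(0, lab)
            self.sigma.insert(0, sig)
        elif direction < 0 and self.cuts[j] == 0:
            assert j == 0
            self.cuts.pop(0)
            lab = self.labels.pop(0)
            sig = self.sigma.pop(0)
            self.cuts.append(n - 1)
            self.labels.append(lab)
            self.sigma.append(sig)
        else:
            self.cuts[j] = new

    def copy(self) -> "DomainPartition":
        return DomainPartition(
            self.n_sites, list(self.cuts), list(self.labels), list(self.sigma)
        )


def discretize(
    spec: GenomeSpec, unit_length: int = DEFAULT_UNIT_LENGTH
) -> dict:
    """Map the genome onto the lattice.

    Returns a dict with ``n_sites``, per-unit site coordinates
    (``tss_site``, ``term_site``) and ``barrier_sites``, validating that no
    two elements collide after rounding and that no transcribed span crosses
    a fixed barrier.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be > 0")
    n_sites = math.ceil(spec.length / unit_length)
    barrier_sites = [b // unit_length for b in spec.barriers]
    if len(set(barrier_sites)) != len(barrier_sites):
        raise ValueError("two barriers collide on the same lattice site")
    occupied: dict[int, str] = {s: f"barrier@{b}" for s, b in zip(barrier_sites, spec.barriers)}
    units = {}
    bset = set(barrier_sites)
    for u in spec.units:
        tss_site = u.tss // unit_length
        term_site = u.terminator // unit_length
        span = _arc_sites(tss_site, term_site, u.direction, n_sites)
        if len(span) < 1:
            raise ValueError(f"unit {u.id}: transcribed span shorter than one unit")
        for s in span:
            if s in bset:
                raise ValueError(
                    f"unit {u.id} spans fixed barrier at site {s}"
                )
            if s in occupied:
                raise ValueError(
                    f"unit {u.id} collides with {occupied[s]} at site {s}"
                )
        for s in span:
            occupied[s] = f"unit {u.id}"
        units[u.id] = {"tss_site": tss_site, "term_site": term_site}
    return {
        "n_sites": n_sites,
        "unit_length": unit_length,
        "units": units,
        "barrier_sites": barrier_sites,
    }


def _arc_sites(start: int, end: int, direction: int, n: int) -> list[int]:
    """Lattice sites from start to end (inclusive) walking in ``direction``."""
    sites = []
    s = start
    for _ in range(n + 1):
        sites.append(s)
        if s == end:
            return sites
        s = (s + direction) % n
    raise ValueError("arc does not close")


def partition_domains(
    spec: GenomeSpec,
    rnap_positions: dict[str, int] | None = None,
    sigma0: float = 0.0,
    unit_length: int = DEFAULT_UNIT_LENGTH,
) -> DomainPartition:
    """Partition of the circle whose cut points are the fixed barriers plus
    the given elongating-RNAP lattice positions, all domains at ``sigma0``."""
    lat = discretize(spec, unit_length)
    cut_sites: list[int] = list(lat["barrier_sites"])
    labels: list[str] = [f"barrier:{b}" for b in lat["barrier_sites"]]
    for rid, site in (rnap_positions or {}).items():
        if not 0 <= site < lat["n_sites"]:
            raise ValueError(f"RNAP {rid} at invalid site {site}")
        cut_sites.append(site)
        labels.append(f"rnap:{rid}")
    if len(set(cut_sites)) != len(cut_sites):
        raise ValueError("duplicate cut point (barrier/RNAP collision)")
    return DomainPartition.uniform(lat["n_sites"], cut_sites, labels, sigma0)
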