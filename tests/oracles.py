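"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately use plain Python loops over all atom pairs (no candidate
pre-filtering, no vectorisation) so they share no code path with the
package's detectors.
"""

import math

import numpy as np

from mempsn.interactions import (
    DEFAULT_CUTOFFS,
    HBOND,
    HYDROPHOBIC_CLASS,
    INTRA_PROTEIN,
    PROTEIN_LIPID,
    SALTBRIDGE,
    PersistenceTable,
    canonical_pair,
)
from mempsn.trajectory_io import HYDROPHOBIC_RESIDUES, assign_leaflets



def _mi_dist(p, q, box):
    d = 0.0
    for k in range(3):
        dx = p[k] - q[k]
        dx -= box[k] * round(dx / box[k])
        d += dx * dx
    return math.sqrt(d)


def brute_force_recount(trajectory, topology, scope,
                        cutoffs=DEFAULT_CUTOFFS):
    """Frame-by-frame recount over all atom pairs with plain Python loops
    (no candidate pre-filtering, no vectorisation)."""
    res = topology.residues
    lipid = {r.index for r in topology.lipid_residues}
    protein_side = {r.index for r in res
                    if r.molecule_class in ("protein", "myristoyl")}
    hydro_groups = {}
    for r in res:
        ats = [i for i in r.atom_indices
               if "hydrophobic" in topology.atoms[i].roles]
        if not ats:
            continue
        if r.molecule_class == "protein" and \
                r.resname not in HYDROPHOBIC_RESIDUES:
            continue
        hydro_groups[r.index] = ats

    def eligible(ra, rb):
        if ra == rb:
            return None
        if scope == INTRA_PROTEIN:
            if ra not in protein_side or rb not in protein_side:
                return None
            a, b = res[ra], res[rb]
            if (a.molecule_class == "protein"
                    and b.molecule_class == "protein"
                    and a.chain == b.chain
                    and abs(a.resid - b.resid) <= 1):
                return None
            return (ra, rb)
        if ra in protein_side and rb in lipid:
            return (ra, rb)
        if rb in protein_side and ra in lipid:
            return (rb, ra)
        return None

    counts = {}
    n = topology.n_atoms
    resindex = topology.atom_resindex
    for f in range(trajectory.n_frames):
        xyz = trajectory.coords[f]
        box = trajectory.box[f]
        upper = None
        if scope == PROTEIN_LIPID:
            leaf = assign_leaflets(topology, xyz)
            upper = set(leaf.residues("upper"))
        frame_hits = set()
        for i in range(n):
            ai = topology.atoms[i]
            for j in range(n):
                if j == i:
                    continue
                aj = topology.atoms[j]
                pair = eligible(resindex[i], resindex[j])
                if pair is None:
                    continue
                if upper is not None and pair[1] not in upper:
                    continue
                d = _mi_dist(xyz[i], xyz[j], box)
                keys = (res[pair[0]].node_key, res[pair[1]].node_key)
                if ("charged_positive" in ai.roles
                        and "charged_negative" in aj.roles
                        and d <= cutoffs.saltbridge_distance):
                    frame_hits.add((*canonical_pair(*keys), SALTBRIDGE))
                if ("hbond_donor" in ai.roles
                        and "hbond_acceptor" in aj.roles
                        and d <= cutoffs.hbond_distance):
                    for h in range(n):
                        ah = topology.atoms[h]
                        if ah.element != "H" or \
                                resindex[h] != resindex[i]:
                            continue
                        if _mi_dist(xyz[i], xyz[h], box) > 1.3:
                            continue
                        v1 = xyz[i] - xyz[h]
                        v2 = xyz[j] - xyz[h]
                        cosang = float(np.dot(v1, v2)
                                       / (np.linalg.norm(v1)
                                          * np.linalg.norm(v2)))
                        ang = math.degrees(
                            math.acos(max(-1.0, min(1.0, cosang)))
                        )
                        if ang >= cutoffs.hbond_angle:
                            frame_hits.add(
                                (*canonical_pair(*keys), HBOND)
                            )
                            break
        for ra, ats_a in hydro_groups.items():
            for rb, ats_b in hydro_groups.items():
                pair = eligible(ra, rb)
                if pair is None:
                    continue
                if upper is not None and pair[1] not in upper:
                    continue
                com_a = np.mean([xyz[i] for i in ats_a], axis=0)
                com_b = np.mean([xyz[i] for i in ats_b], axis=0)
                if _mi_dist(com_a, com_b, box) <= \
                        cutoffs.hydrophobic_distance:
                    keys = (res[pair[0]].node_key, res[pair[1]].node_key)
                    frame_hits.add(
                        (*canonical_pair(*keys), HYDROPHOBIC_CLASS)
                    )
        for key in frame_hits:
            counts[key] = counts.get(key, 0) + 1
    return PersistenceTable(counts, trajectory.n_frames)


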