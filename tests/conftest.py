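import numpy as np
import pytest

import malkit as mk


@pytest.fixture(scope="session")
def pocket():
    """Analytic pocket fixture: receptor, reference pose, anchors, template."""
    receptor, reference = mk.make_pocket_fixture()
    anchors = mk.anchors_from_structure(receptor)
    template = mk.get_template("3-methylaspartate")
    return receptor, reference, anchors, template


@pytest.fixture(scope="session")
def extended_pocket():
    receptor, reference = mk.make_pocket_fixture(extended=True)
    anchors = mk.anchors_from_structure(receptor)
    template = mk.get_template("3-methylaspartate")
    return receptor, reference, anchors, template


def brute_force_scaffold_rmsd(pose, reference, template, reference_template=None):
    """Independent oracle: exhaustive enumeration over every symmetry mapping.

    Builds the 6-atom coordinate arrays straight from the template labels
    and tries every (pose carboxyl) x (reference carboxyl) x (oxygen
    permutation) combination.
    """
    ref_template = reference_template or template
    best = np.inf
    for pc in range(len(template.carboxyl_groups)):
        g = template.carboxyl_groups[pc]
        backs = template.backbone_carbons[pc]
        for o_order in ((g.oxygen1, g.oxygen2), (g.oxygen2, g.oxygen1)):
            labels_p = (g.carbon,) + o_order + backs
            p = np.array([pose.atom(n).position for n in labels_p])
            for rc in range(len(ref_template.carboxyl_groups)):
                rg = ref_template.carboxyl_groups[rc]
                labels_r = (rg.carbon, rg.oxygen1, rg.oxygen2) + ref_template.backbone_carbons[rc]
                r = np.array([reference.atom(n).position for n in labels_r])
                rmsd = np.sqrt(np.mean(np.sum((p - r) ** 2, axis=1)))
                best = min(best, rmsd)
    return float(best)
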