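import io

import pytest

from longmeta.taxonomy import load_taxonomy


NODES_DMP = """\
1\t|\t1\t|\tno rank\t|
2\t|\t1\t|\tsuperkingdom\t|
2157\t|\t1\t|\tsuperkingdom\t|
2759\t|\t1\t|\tsuperkingdom\t|
10239\t|\t1\t|\tsuperkingdom\t|
4751\t|\t2759\t|\tkingdom\t|
33090\t|\t2759\t|\tkingdom\t|
33208\t|\t2759\t|\tkingdom\t|
7711\t|\t33208\t|\tphylum\t|
9606\t|\t7711\t|\tspecies\t|
4930\t|\t4751\t|\tgenus\t|
4932\t|\t4930\t|\tspecies\t|
561\t|\t2\t|\tgenus\t|
562\t|\t561\t|\tspecies\t|
621\t|\t561\t|\tspecies\t|
1301\t|\t2\t|\tgenus\t|
1311\t|\t1301\t|\tspecies\t|
2093\t|\t2157\t|\tspecies\t|
10759\t|\t10239\t|\tspecies\t|
5755\t|\t2759\t|\tspecies\t|
"""

NAMES_DMP = """\
1\t|\troot\t|\t\t|\tscientific name\t|
2\t|\tBacteria\t|\t\t|\tscientific name\t|
562\t|\tEscherichia coli\t|\t\t|\tscientific name\t|
562\t|\tE. coli\t|\t\t|\tsynonym\t|
621\t|\tShigella boydii\t|\t\t|\tscientific name\t|
9606\t|\tHomo sapiens\t|\t\t|\tscientific name\t|
4932\t|\tSaccharomyces cerevisiae\t|\t\t|\tscientific name\t|
"""


@pytest.fixture(scope="session")
def ncbi_tree():
    """Miniature NCBI-shaped taxonomy covering every domain label."""
    return load_taxonomy(io.StringIO(NODES_DMP), io.StringIO(NAMES_DMP))
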