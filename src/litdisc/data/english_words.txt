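# Pinned English word list for gene-symbol screening.
# One word per line; comparison is case-insensitive. This is a deliberately
# small, versioned lexicon of common English words and laboratory terms that
# collide with gene symbols; extend via the configurable dictionary path.
ACT
AGE
AID
AIM
ALL
AND
ANY
ARE
ARM
ART
ASK
BAD
BAG
BAR
BED
BIG
BIT
BOX
BOY
BUT
CAN
CAR
CAT
CELL
CELLS
CAMP
CAST
COLD
CUT
DAY
DID
DOG
EAR
EAT
END
EYE
FAR
FAT
FEW
FIT
FOR
GAS
GET
GOT
HAD
HAS
HER
HIM
HIS
HIT
HOT
HOW
ITS
JOB
KIT
LAB
LAW
LET
LOW
MAN
MAP
MAX
MEN
MET
MICE
MIX
NET
NEW
NOT
NOW
OLD
ONE
OUR
OUT
OWN
PER
PUT
RAN
RAT
RATS
RAW
RED
RUN
SAW
SAY
SEE
SET
SHE
SIT
SIX
SON
SUM
SUN
TEN
THE
TIP
TOO
TOP
TRY
TWO
USE
VIA
WAR
WAS
WAY
WHO
WHY
WIN
YES
YET
YOU
BLOOD
BRAIN
CLONE
GENE
GROUP
HUMAN
LARGE
LEVEL
LIGHT
LIVER
MAJOR
MODEL
MOUSE
PLATE
PRIOR
RANGE
SCALE
SERUM
SHARP
SMALL
STAGE
STUDY
TISSUE
TOTAL
TRACE
TYPE
UNIT
WHITE
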