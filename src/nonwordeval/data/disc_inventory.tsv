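symbol	ipa	category	place	manner	position	length	is_schwa	example
p	p	consonant	bilabial	plosive			false	pat
b	b	consonant	bilabial	plosive			false	bad
t	t	consonant	alveolar	plosive			false	tack
d	d	consonant	alveolar	plosive			false	dad
k	k	consonant	velar	plosive			false	cad
g	g	consonant	velar	plosive			false	game
m	m	consonant	bilabial	nasal			false	mad
n	n	consonant	alveolar	nasal			false	nat
N	ŋ	consonant	velar	nasal			false	bang
f	f	consonant	labiodental	fricative			false	fat
v	v	consonant	labiodental	fricative			false	vat
T	θ	consonant	dental	fricative			false	thin
D	ð	consonant	dental	fricative			false	then
s	s	consonant	alveolar	fricative			false	sap
z	z	consonant	alveolar	fricative			false	zap
S	ʃ	consonant	postalveolar	fricative			false	sheep
Z	ʒ	consonant	postalveolar	fricative			false	measure
x	x	consonant	velar	fricative			false	loch
h	h	consonant	glottal	fricative			false	had
J	tʃ	consonant	postalveolar	affricate			false	cheap
_	dʒ	consonant	postalveolar	affricate			false	jeep
l	l	consonant	alveolar	lateral			false	lad
r	r	consonant	postalveolar	approximant			false	rat
j	j	consonant	palatal	approximant			false	yank
w	w	consonant	labial-velar	approximant			false	why
F	m̩	consonant	bilabial	nasal			false	idealism
H	n̩	consonant	alveolar	nasal			false	burden
P	l̩	consonant	alveolar	lateral			false	dangle
C	ŋ̩	consonant	velar	nasal			false	bacon
I	ɪ	vowel			front	short	false	pit
E	ɛ	vowel			front	short	false	pet
{	æ	vowel			front	short	false	pat
V	ʌ	vowel			mid	short	false	putt
Q	ɒ	vowel			back	short	false	pot
U	ʊ	vowel			back	short	false	put
@	ə	vowel			mid	short	true	another
i	iː	vowel			front	long	false	bean
#	ɑː	vowel			back	long	false	barn
$	ɔː	vowel			back	long	false	born
u	uː	vowel			back	long	false	boon
3	ɜː	vowel			mid	long	false	burn
1	eɪ	diphthong			front	diphthong	false	bay
2	aɪ	diphthong			front	diphthong	false	buy
4	ɔɪ	diphthong			back	diphthong	false	boy
5	əʊ	diphthong			mid	diphthong	false	no
6	aʊ	diphthong			mid	diphthong	false	brow
7	ɪə	diphthong			front	diphthong	false	peer
8	ɛə	diphthong			front	diphthong	false	pair
9	ʊə	diphthong			back	diphthong	false	poor
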