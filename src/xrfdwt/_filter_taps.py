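"""Low-pass decomposition taps for the supported orthogonal wavelet families.

Standard published coefficient tables (Daubechies extremal-phase, least-
asymmetric Symlets, Coiflets, Haar), orthonormal convention: sum of taps
is sqrt(2) and the squared taps sum to 1. Validated at load time by the
filter-bank invariants in :mod:`xrfdwt.wavelet`.
"""

LOWPASS_DEC_TAPS = {
    "haar": (
        0.7071067811865476,
        0.7071067811865476,
    ),
    "db1": (
        0.7071067811865476,
        0.7071067811865476,
    ),
    "db2": (
        -0.12940952255126037,
        0.2241438680420134,
        0.8365163037378079,
        0.48296291314453416,
    ),
    "db3": (
        0.03522629188570953,
        -0.08544127388202666,
        -0.13501102001025458,
        0.45987750211849154,
        0.8068915093110925,
        0.33267055295008263,
    ),
    "db4": (
        -0.010597401785069032,
        0.0328830116668852,
        0.030841381835560764,
        -0.18703481171909309,
        -0.027983769416859854,
        0.6308807679298589,
        0.7148465705529157,
        0.2303778133088965,
    ),
    "db5": (
        0.0033357252854737712,
        -0.012580751999081999,
        -0.006241490212798274,
        0.07757149384004572,
        -0.032244869584638375,
        -0.24229488706638203,
        0.13842814590132074,
        0.7243085284377729,
        0.6038292697971896,
        0.16010239797419293,
    ),
    "db6": (
        -0.0010773010853084796,
        0.004777257510945511,
        0.0005538422011614961,
        -0.03158203931748603,
        0.027522865530305727,
        0.09750160558732304,
        -0.12976686756726194,
        -0.22626469396543983,
        0.31525035170919763,
        0.7511339080210954,
        0.49462389039845306,
        0.11154074335010947,
    ),
    "db7": (
        0.00035371379997452024,
        -0.0018016407040474908,
        0.0004295779729213665,
        0.01255099855609984,
        -0.01657454163066688,
        -0.03802993693501441,
        0.08061260915108308,
        0.07130921926683026,
        -0.22403618499387498,
        -0.14390600392856498,
        0.4697822874051931,
        0.7291320908462351,
        0.3965393194819173,
        0.07785205408500918,
    ),
    "db8": (
        -0.00011747678412476953,
        0.0006754494064505693,
        -0.00039174037337694705,
        -0.004870352993451574,
        0.008746094047405777,
        0.013981027917398282,
        -0.044088253930794755,
        -0.017369301001807547,
        0.12874742662047847,
        0.0004724845739132828,
        -0.2840155429615469,
        -0.015829105256349306,
        0.5853546836542067,
        0.6756307362972898,
        0.31287159091429995,
        0.05441584224310401,
    ),
    "db9": (
        3.93473203162716e-05,
        -0.0002519631889427101,
        0.00023038576352319597,
        0.0018476468830562265,
        -0.00428150368246343,
        -0.004723204757751397,
        0.022361662123679096,
        0.00025094711483145197,
        -0.06763282906132997,
        0.03072568147933338,
        0.14854074933810638,
        -0.09684078322297646,
        -0.2932737832791749,
        0.13319738582500756,
        0.6572880780513005,
        0.6048231236901112,
        0.24383467461259034,
        0.038077947363878345,
    ),
    "db10": (
        -1.3264202894521244e-05,
        9.358867032006959e-05,
        -0.00011646685512928545,
        -0.0006858566949597116,
        0.001992405295185056,
        0.001395351747052901,
        -0.010733175483330575,
        0.0036065535669561697,
        0.033212674059341,
        -0.029457536821875813,
        -0.07139414716639708,
        0.09305736460357235,
        0.12736934033579325,
        -0.19594627437737705,
        -0.24984642432731538,
        0.2811723436605775,
        0.6884590394536035,
        0.5272011889317256,
        0.1881768000776915,
        0.026670057900555554,
    ),
    "sym2": (
        -0.12940952255092145,
        0.22414386804185735,
        0.836516303737469,
        0.48296291314469025,
    ),
    "sym3": (
        0.035226291882100656,
        -0.08544127388224149,
        -0.13501102001039084,
        0.4598775021193313,
        0.8068915093133388,
        0.3326705529509569,
    ),
    "sym4": (
        -0.07576571478927333,
        -0.02963552764599851,
        0.49761866763201545,
        0.8037387518059161,
        0.29785779560527736,
        -0.09921954357684722,
        -0.012603967262037833,
        0.0322231006040427,
    ),
    "sym5": (
        0.027333068345077982,
        0.029519490925774643,
        -0.039134249302383094,
        0.1993975339773936,
        0.7234076904024206,
        0.6339789634582119,
        0.01660210576452232,
        -0.17532808990845047,
        -0.021101834024758855,
        0.019538882735286728,
    ),
    "sym6": (
        0.015404109327027373,
        0.0034907120842174702,
        -0.11799011114819057,
        -0.048311742585633,
        0.4910559419267466,
        0.787641141030194,
        0.3379294217276218,
        -0.07263752278646252,
        -0.021060292512300564,
        0.04472490177066578,
        0.0017677118642428036,
        -0.007800708325034148,
    ),
    "sym7": (
        0.002681814568257878,
        -0.0010473848886829163,
        -0.01263630340325193,
        0.03051551316596357,
        0.0678926935013727,
        -0.049552834937127255,
        0.017441255086855827,
        0.5361019170917628,
        0.767764317003164,
        0.2886296317515146,
        -0.14004724044296152,
        -0.10780823770381774,
        0.004010244871533663,
        0.010268176708511255,
    ),
    "sym8": (
        -0.0033824159510061256,
        -0.0005421323317911481,
        0.03169508781149298,
        0.007607487324917605,
        -0.1432942383508097,
        -0.061273359067658524,
        0.4813596512583722,
        0.7771857517005235,
        0.3644418948353314,
        -0.05194583810770904,
        -0.027219029917056003,
        0.049137179673607506,
        0.003808752013890615,
        -0.01495225833704823,
        -0.0003029205147213668,
        0.0018899503327594609,
    ),
    "coif1": (
        -0.015655728135791993,
        -0.07273261951252645,
        0.3848648468648578,
        0.8525720202116004,
        0.3378976624574818,
        -0.07273261951252645,
    ),
    "coif2": (
        -0.000720549445520347,
        -0.0018232088709110323,
        0.005611434819368834,
        0.02368017194684777,
        -0.05943441864643109,
        -0.07648859907828076,
        0.4170051844232391,
        0.8127236354494135,
        0.3861100668227629,
        -0.0673725547237256,
        -0.04146493678687178,
        0.01638733646320364,
    ),
    "coif3": (
        -3.459977319727278e-05,
        -7.0983302506379e-05,
        0.0004662169598204029,
        0.0011175187708306303,
        -0.0025745176881367972,
        -0.009007976136730624,
        0.015880544863669452,
        0.03455502757329774,
        -0.08230192710629983,
        -0.07179982161915484,
        0.42848347637737,
        0.7937772226260872,
        0.40517690240911824,
        -0.06112339000297255,
        -0.06577191128146936,
        0.023452696142077168,
        0.007782596425672746,
        -0.003793512864380802,
    ),
    "coif4": (
        -1.7849909144933469e-06,
        -3.259647940030751e-06,
        3.1229861599195265e-05,
        6.233885431278719e-05,
        -0.0002599743371222568,
        -0.0005890202246332165,
        0.0012665610789256603,
        0.0037514346971460866,
        -0.0056582838001308835,
        -0.015211728187697211,
        0.02508225333794961,
        0.03933442260558915,
        -0.09622042453595264,
        -0.06662747236681717,
        0.43438603311435653,
        0.7822389344242826,
        0.41530842700068227,
        -0.05607731960356926,
        -0.08126671024919373,
        0.02668230466960483,
        0.01606894713157503,
        -0.007346167936268051,
        -0.001629492425226786,
        0.000892313902537003,
    ),
    "coif5": (
        -9.604010112767894e-08,
        -1.6237995172048338e-07,
        2.0612203985788783e-06,
        3.7007277113394796e-06,
        -2.1270221672515614e-05,
        -4.12198619242655e-05,
        0.00014035632812373243,
        0.0003018579416682448,
        -0.0006375589261258812,
        -0.0016616273039298788,
        0.0024315754425382886,
        0.006761520220620417,
        -0.009159507338676163,
        -0.019758391600965465,
        0.032674799467057355,
        0.041287530472117834,
        -0.10556315130733723,
        -0.06203775157498196,
        0.4379823066591634,
        0.7742936228603274,
        0.42157126673075435,
        -0.052046670253554764,
        -0.09192158806008609,
        0.028169744270532353,
        0.023408322118927783,
        -0.010131584846900276,
        -0.00415931262757864,
        0.0021782943778456947,
        0.0003585777411617577,
        -0.000212081862067494,
    ),
}
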