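"""Frozen two-batch location/scale adjustment reference (generated
once with the standard R implementation) for regression pinning."""

BATCH = ['A', 'A', 'A', 'A', 'A', 'B', 'B', 'B', 'B', 'B', 'B', 'B']

INPUT = [
    [-0.16754079848027154, 0.22078750168032832, 1.255591760633911, 0.5718828485777858, 1.0257862682071488, 1.6496508614196044, 0.8911827104633889, 1.6276814626727125, 1.0910973019764192, 1.0874763162459535, 1.3496951130593984, 0.3352744123428222],
    [1.472047085175302, -1.5735248624617266, 1.1583836764892017, -0.2537770816753845, 2.027574317725211, -1.762754342255144, -1.1936480088924246, -0.13190765799080928, -4.292212600952143, 0.6692674448784884, 1.8358555164747177, 1.1578084454437056],
    [-2.6022585258571302, -3.4100005677728413, -2.129554320675753, -2.315962418142697, -2.9270141303084047, -3.9119589729320277, -4.240958326458501, -5.01975141159159, -2.81692860496707, -5.864317582395003, -4.248473485424174, -3.769137991140398],
    [2.2258201237437674, 3.1009621840833637, 2.3553209084147086, 1.1084291913360702, 2.097958412780788, 0.9358208015530047, 3.5478533521944486, 2.0083011258559846, 1.5062975257813624, 1.5399715881597769, 2.100605517940678, 1.7789719587168777],
    [-0.4356093024273191, -6.399192875776423, -4.910743172641979, -4.919779170570911, -4.919338602062912, -4.767187033851203, -5.831616242443005, -6.033524700823799, -6.586156509102993, -7.82723842849127, -4.44807960885583, -2.9253708166964603],
    [-3.4090472748977785, -3.4261442581704857, -3.159596223982043, -3.3182894500101225, -4.392298814440098, -0.01770102077846758, -1.037194898281189, -2.3039221454820424, -1.1933245112152338, -2.003131984462757, -1.7534403703884842, -1.1197973460815809],
    [-1.3207000523876757, -0.6623758023548179, -0.4481259346810811, -2.7171803245045516, -3.0087063769535733, -2.2889500369381413, -2.2555484372233296, -3.257821610825051, -3.1256516802743137, -1.4596810060976575, -0.49695868504077456, -2.6678659317142985],
    [-2.455151594006805, -1.7693874257707098, -3.1081357422294182, -1.7496390550303875, -0.44182068218867177, -2.3201053671003073, 0.1550071047148287, -1.883302533265188, -1.262170743227474, -2.446905304924856, 0.30752557539061076, -4.466215060120728],
    [2.0116961526027084, 0.5454955091399694, 3.915630918051956, 3.956155511227315, 1.6541580409390089, 6.13271042378601, 2.8377073170561014, 1.0074962019733897, 2.864766798921969, 3.9452947939424954, 2.9436505054176965, 7.156252171197263],
    [6.5005188772025555, 8.06768651409088, 7.449699587630271, 1.9537963540231567, 4.294146858100742, 1.5526263160860898, 5.277948028963646, 8.429666349430411, 4.925803223385132, 5.29531834020664, 7.018022817470577, 7.843180916694407],
    [4.738406633040803, 4.859262861160583, 6.139714842665553, 5.472400452306076, 4.823818626162315, 5.710992020217823, 5.424329324061585, 5.638995561574152, 7.739341221955806, 4.965767308725063, 4.683706774211643, 7.0327311480811225],
    [1.8409819500867508, 3.8269468632359325, 2.259777640548097, 2.4792346366216296, 3.0194402232653648, 4.793641673556422, 4.616699598006893, 3.63367406872905, 3.5003860341114086, 4.084896699067388, 3.9107035700141797, 3.2745370579418003],
    [1.564885197775502, 1.9140206663232529, 1.4187289103187644, 2.2550700974288853, 1.5646302871481805, 0.6323083023243506, 0.7855302993020657, 0.39035351740880875, 0.10836712298507145, 1.0107382811158243, 0.21492120386399338, 0.5111330964768913],
    [-7.06492574950876, -6.770989445526334, -6.723854819773984, -6.976043130737957, -8.206518566411475, -7.605527219874566, -7.958115461193563, -7.546501799855101, -6.863151711132603, -6.978730842712525, -7.340954080000971, -7.164067398470804],
    [2.340310276436295, 3.5278348813864904, 3.830941506178162, 2.8921972030139558, 3.676071344807027, 2.9754720898785543, 3.9499808771274383, 4.026111126580071, 2.8668579501774927, 4.276208004415324, 3.1100403717310536, 4.698808616607156],
]

EXPECTED = [
    [0.16001624509412, 0.52236998498626, 1.48795810496892, 0.84998121485131, 1.27352387600813, 1.42189332413784, 0.72628323691884, 1.40174463976763, 0.90962990251503, 0.90630900605205, 1.14679641464252, 0.21644585053168],
    [0.955175523249, -2.15232914337554, 0.63513366477389, -0.80574385231293, 1.52199958692782, -1.27406998376399, -0.76879091741276, 0.17387153731883, -3.51984064629893, 0.88519204849585, 1.92094318510626, 1.31894146608062],
    [-3.38291091416688, -4.23090186343218, -2.88665237261224, -3.08234898281571, -3.72384873714403, -3.44339075993527, -3.7314800527435, -4.41343260594776, -2.48452406026203, -5.15297956331566, -3.7380607247374, -3.31832912926183],
    [2.0995743355266, 2.96516074041054, 2.22766110419301, 0.99438416827835, 1.9731087435611, 1.11857439951891, 3.46363965582658, 2.0814400215338, 1.63074456569529, 1.66097691241814, 2.16431028393893, 1.87554983766766],
    [-1.31420046762062, -6.79403815130531, -5.42632649384549, -5.43462952194121, -5.43422469087233, -4.44485654204789, -5.42872220783866, -5.61534880379276, -6.12615352204084, -7.27330157008739, -4.14990142749669, -2.74244202342292],
    [-2.32397253500673, -2.34135142448563, -2.07040837253944, -2.23171823593478, -3.32343656694195, -0.89497534710317, -1.7884009464179, -2.89848760311359, -1.92522392896298, -2.63489246457789, -2.41607714369081, -1.860788964688],
    [-1.62376870745102, -1.00441096055179, -0.80284263717734, -2.93759069545216, -3.21186119209304, -2.09391059854583, -2.06334467940655, -2.98052831855405, -2.85957915910207, -1.33504364732796, -0.45405312980029, -2.44065784116905],
    [-2.37313568858305, -1.65971263562553, -3.05245660696248, -1.63916775504255, -0.27860122286781, -2.31762332698226, -0.13279686033216, -1.93204957914733, -1.38376533364113, -2.42955192145357, 0.00183394743112, -4.21203310069518],
    [2.71126863962203, 1.21569088751305, 4.65335104789856, 4.69468760046151, 2.3465668181357, 5.40745409985615, 2.48223115538684, 0.85741461541823, 2.5062538997229, 3.46552015252845, 2.5762849196375, 6.3161293596865],
    [6.52468726334614, 8.02339341899153, 7.43240315796632, 2.17658762607287, 4.41470027226888, 1.89064498315355, 5.27889938086192, 8.14545005291406, 4.95861665682037, 5.29469802538038, 6.86153210600875, 7.6120298546556],
    [5.05238542406047, 5.17954224063739, 6.52674792693776, 5.82464448672464, 5.14225019405856, 5.50931754766431, 5.25731756614029, 5.4460267655316, 7.29240257482684, 4.85420400814375, 4.60624970352333, 6.67123446349346],
    [2.53694830899032, 4.3646930303296, 2.92237889111806, 3.12435192874758, 3.62151978044965, 4.30492194052654, 4.14233843151999, 3.2390838523214, 3.11661192861744, 3.65369048760436, 3.49363285248086, 2.90909023578575],
    [0.98145972189957, 1.30878312833885, 0.84443447470296, 1.62852566844232, 0.98122073668498, 1.01704040063962, 1.15446594370804, 0.8000299950132, 0.54711504705553, 1.35645606141028, 0.6426839126217, 0.90835777804961],
    [-7.16958883507162, -6.90345463127499, -6.8607782557273, -7.08911321958132, -8.20320357156406, -7.5231607321041, -7.85137211617415, -7.46821614652339, -6.83211076313062, -6.93969911208846, -7.27687935839514, -7.11222207330987],
    [2.5716584369661, 3.74639204419075, 4.0462338640831, 3.1176009103567, 3.89303183141734, 2.90248423181397, 3.77702970803559, 3.84535065714718, 2.80501152990286, 4.06979305929877, 3.02324874792393, 4.44904408143087],
]
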